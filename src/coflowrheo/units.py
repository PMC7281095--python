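"""Unit conversion constants.

User-facing quantities are expressed in the units a microfluidics lab
records them in (um, cP, mL/h, s, gray levels); all internal physics is
done in SI.
"""

#: centipoise -> Pa s
CP_TO_PAS = 1.0e-3

#: mL/h -> m^3/s
MLH_TO_M3S = 1.0e-6 / 3600.0

#: micrometre -> metre
UM_TO_M = 1.0e-6

#: microlitre/Pa -> m^3/Pa (compliance)
ULPA_TO_M3PA = 1.0e-9

#: mm/s -> m/s
MMS_TO_MS = 1.0e-3
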