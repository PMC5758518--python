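# Default anthropometric fractions for the 14-segment planar body model.
#
# Winter-style dimensionless ratios, per segment:
#   mass_fraction      — segment mass / whole-body mass
#   com_fraction       — segment-COM position along the proximal->distal axis,
#                        as a fraction of segment length
#   gyration_fraction  — radius of gyration about the transverse axis through
#                        the segment COM, as a fraction of segment length
#   length_fraction    — segment length as a fraction of body height (used by
#                        the synthetic generator to scale the chain)
#
# The trunk gyration ratio follows de Leva-style trunk values; everything else
# follows the classic Winter gait-analysis table. Mass fractions sum to 1.000.
# Override with your own table via AnthropometricTable.from_yaml().

He:  {mass_fraction: 0.0810, com_fraction: 0.500, gyration_fraction: 0.495, length_fraction: 0.130}
Tr:  {mass_fraction: 0.4970, com_fraction: 0.500, gyration_fraction: 0.372, length_fraction: 0.288}
LUA: {mass_fraction: 0.0280, com_fraction: 0.436, gyration_fraction: 0.322, length_fraction: 0.186}
RUA: {mass_fraction: 0.0280, com_fraction: 0.436, gyration_fraction: 0.322, length_fraction: 0.186}
LFA: {mass_fraction: 0.0160, com_fraction: 0.430, gyration_fraction: 0.303, length_fraction: 0.146}
RFA: {mass_fraction: 0.0160, com_fraction: 0.430, gyration_fraction: 0.303, length_fraction: 0.146}
LA:  {mass_fraction: 0.0060, com_fraction: 0.506, gyration_fraction: 0.297, length_fraction: 0.108}
RA:  {mass_fraction: 0.0060, com_fraction: 0.506, gyration_fraction: 0.297, length_fraction: 0.108}
LT:  {mass_fraction: 0.1000, com_fraction: 0.433, gyration_fraction: 0.323, length_fraction: 0.245}
RT:  {mass_fraction: 0.1000, com_fraction: 0.433, gyration_fraction: 0.323, length_fraction: 0.245}
LS:  {mass_fraction: 0.0465, com_fraction: 0.433, gyration_fraction: 0.302, length_fraction: 0.246}
RS:  {mass_fraction: 0.0465, com_fraction: 0.433, gyration_fraction: 0.302, length_fraction: 0.246}
LF:  {mass_fraction: 0.0145, com_fraction: 0.500, gyration_fraction: 0.475, length_fraction: 0.152}
RF:  {mass_fraction: 0.0145, com_fraction: 0.500, gyration_fraction: 0.475, length_fraction: 0.152}
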