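"""Built-in miRNA definitions used throughout the examples and CLI.

miR-99a-5p and miR-100-5p differ by a single nucleotide towards the 3' end
and share an identical 1-8 seed, so the pair is treated as one functional
unit through the miR-100-5p sequence.
"""

from .seed_scan import MiRNA

__all__ = ["MIR_100_5P", "MIR_125B_5P", "DEFAULT_MIRNAS"]

#: miR-100-5p, surrogate for the miR-99a-5p/miR-100-5p unit.
MIR_100_5P = MiRNA(name="miR-100-5p", mature_seq="AACCCGUAGAUCCGAACUUGUG")

#: miR-125b-5p (2-7 seed CCCUGA; canonical SCR word TCAGGG).
MIR_125B_5P = MiRNA(name="miR-125b-5p", mature_seq="UCCCUGAGACCCUAACUUGUGA")

DEFAULT_MIRNAS = (MIR_100_5P, MIR_125B_5P)
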