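"""Shared constants."""

#: Sentinel for a missing genotype call in integer genotype matrices.
MISSING: int = -1
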