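"""Rank transcription-factor motifs by allelic affinity difference.

Scans the packaged rs72664324 allele probe sequences (protective A vs
risk G) against the packaged synthetic motif set.  Per motif and allele,
the best log-odds match gets an exact p-value from the discretised null
score distribution (Sidak-corrected over offsets and strands); motifs are
ranked by |log10(p_G) - log10(p_A)|.
"""

from chromadelta.pipeline import allele_scan_packaged

table = allele_scan_packaged()
print(table.to_string(index=False))
# diff_logp > 0 means the motif matches the protective A allele better.
# The CEBP-like matrix spans the variant (the A allele restores its core),
# so it tops the ranking; the near-uniform control is indifferent (diff 0)
# and ranks last.
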