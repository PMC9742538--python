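"""Filter a differential-expression table by log2-fold-change cutoff.

Loads the packaged biofilm-vs-planktonic table (38 genes) and applies the
symmetric cutoff |log2FC| >= 2 at the table's printed precision, recovering
the published 27 up- / 11 down-regulated gene counts.
"""

from biofilmoct import filter_de, load_biofilm_vs_planktonic_table

records = load_biofilm_vs_planktonic_table()
result = filter_de(records, lfc_cutoff=2.0, printed_precision=1)

print(f"table size           : {len(records)} genes")
print(f"upregulated  (>= +2) : {result.n_up}")
print(f"downregulated (<= -2): {result.n_down}")

by_tag = {r.locus_tag: r for r in records}
print("\nstrongest upregulation in biofilm:")
for tag in sorted(result.up, key=lambda t: -by_tag[t].log2fc)[:5]:
    r = by_tag[tag]
    print(f"  {tag}  log2FC {r.log2fc:+.1f}  {r.annotation}")

# a stricter cutoff keeps fewer genes (monotone filtering)
strict = filter_de(records, lfc_cutoff=2.5, printed_precision=1)
print(f"\nat cutoff 2.5: {strict.n_up} up / {strict.n_down} down")
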