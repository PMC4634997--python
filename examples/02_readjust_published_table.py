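"""Re-adjust the bundled published p-value tables.

For each of the four CD4- vs CD4+ TRB comparisons (Pre, d3, d8, d26) the
bundled data holds the printed per-gene unadjusted p-values (< 0.05) and
the derived family size m.  The script re-runs all seven adjustment
procedures, treating the printed values as the m smallest of the family,
and prints how many hypotheses each of the headline procedures rejects at
alpha = 0.05.  Bonferroni (FWER, most conservative) keeps the fewest;
Benjamini-Hochberg (FDR) keeps the most - the gap is the price of
family-wise control.
"""

from clonostat import adjust_table
from clonostat.datasets import COMPARISONS, FAMILY_SIZES

print(f"{'comparison':<12}{'m':>4}{'supplied':>10}"
      f"{'bonferroni':>12}{'holm':>7}{'bh':>5}{'by':>5}")
for name, rows in COMPARISONS.items():
    table = adjust_table(dict(rows), m=FAMILY_SIZES[name], alpha=0.05)
    counts = {m: int(table[f"sig_{m}"].sum())
              for m in ("bonferroni", "holm", "bh", "by")}
    print(f"{name:<12}{FAMILY_SIZES[name]:>4}{len(rows):>10}"
          f"{counts['bonferroni']:>12}{counts['holm']:>7}"
          f"{counts['bh']:>5}{counts['by']:>5}")

top = adjust_table(dict(COMPARISONS["Pre"]), m=FAMILY_SIZES["Pre"]).iloc[0]
print(f"\ntop Pre gene {top['gene']}: raw {top['raw_p']:.2g} -> "
      f"bonferroni {top['adj_bonferroni']:.3g}, by {top['adj_by']:.3g}")
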