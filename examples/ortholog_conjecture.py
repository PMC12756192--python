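"""Concordance and outlier analysis over a synthetic orthogroup table.

Generates a two-species orthogroup table (all four relationship categories)
whose pair similarities follow a linear identity-similarity trend, with a
third of one-to-two groups planted discordant and 5% of other pairs planted
far below the trend.  Then (1) classifies each one-to-two group as
concordant or discordant — does the paralog with the highest sequence
identity also have the highest embedding similarity? — and (2) fits
similarity on identity per category, flagging pairs more than 3 residual
SDs from the line, the signature of proteins whose functional divergence
outruns their sequence divergence.
"""

from plmsim import (
    SyntheticOrthoSpec,
    bin_summary,
    concordance_from_records,
    concordance_summary,
    fit_by_category,
    gen_ortholog_table,
)

spec = SyntheticOrthoSpec(
    n_one_to_one=120, n_one_to_two=90, n_one_to_many=40, n_many_to_many=30,
    discordance_rate=1 / 3, outlier_rate=0.05, seed=0,
)
data = gen_ortholog_table(spec)

summary = concordance_summary(concordance_from_records(data.groups, data.records))
print("one-to-two groups (n=90):")
for status, fraction in summary.items():
    print(f"  {status:>10}: {fraction:.3f}")

print("\nper-category fit of similarity on identity (3-SD outlier flags):")
truth = set(data.records.loc[data.records["planted_outlier"], "pair_id"])
for category, fit in fit_by_category(data.records, k=3.0).items():
    hits = len(set(fit.flagged_ids) & truth)
    print(
        f"  {category:>13}: slope={fit.slope:.5f} resid_sd={fit.residual_sd:.4f} "
        f"flagged={len(fit.flagged_ids)} (planted recovered: {hits})"
    )

bins = bin_summary(data.records[data.records["category"] == "one-to-one"], bin_width=10)
print("\none-to-one similarity by identity bin:")
for row in bins.itertuples(index=False):
    print(
        f"  [{row.bin_lo:3.0f},{row.bin_hi:3.0f}): n={row.count:3d} "
        f"mean={row.mean_similarity:.3f} median={row.median_similarity:.3f}"
    )
print("\nFlagged pairs lie far below the identity-similarity trend: candidates")
print("for rapid functional change despite conserved sequence.")
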