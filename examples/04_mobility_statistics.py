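"""Retromobility statistics: frequencies from replicate counts, fold
changes, and the genotype-phenotype rank correlation.

Uses the packaged assay and genomic-content tables for ten yeast strains.
The headline number is the Spearman correlation between his3-AI mobility and
the count of full-length elements with a canonical-type gag: strongly
negative, as expected if canonical gag content scales copy number control.
"""

from tyland import simulate as sim
from tyland import stats
from tyland.datasets import load_mobility_his3ai, load_mobility_populated, load_ty1_content

# a simulated quadruplicate assay, the format the frequency estimator takes
counts, titer = sim.simulate_mobility_counts(
    sim.MobilitySimParams(true_frequency=5e-6, n_replicates=4, cells_per_ml=1e7, seed=3)
)
freq, sd = stats.mobility_frequency(counts, titer)
print(f"simulated assay: counts {counts.tolist()}, frequency {freq:.2e} +/- {sd:.2e}")

mob = load_mobility_his3ai()
lo, hi = mob["frequency"].min(), mob["frequency"].max()
ratio, _ = stats.fold_change(hi, lo)
print(f"\nS. cerevisiae mobility range: {lo} to {hi} (x1e-6) = {ratio:.0f}-fold")

pop = load_mobility_populated().pivot(index="strain", columns="condition", values="frequency")
for strain, row in pop.iterrows():
    r, _ = stats.fold_change(row["native"], row["populated"])
    print(f"populating {strain}: {r:.1f}-fold decrease")

content = load_ty1_content().set_index("strain")
y = content.loc[mob["strain"], "full_canonical_gag"].to_numpy()
res = stats.spearman(mob["frequency"].to_numpy(), y)
print(f"\nSpearman(mobility, canonical-gag count): rho = {res.rho:.7f}, "
      f"p = {res.p_value:.5f} ({res.method}, n = {res.n})")
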