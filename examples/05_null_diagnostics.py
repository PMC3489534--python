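"""Null p-value histograms: raw biased data vs normalized + re-inflated.

On data with no true group differences but an injected bias trend, the
per-peptide p-value distribution should be uniform.  Raw biased data fail
this badly; SVD normalization followed by residual re-inflation restores it.
"""

from lcmsprep import run_null_pvalue_experiment

for pipeline in ("raw", "normalized", "normalized_reinflated"):
    rep = run_null_pvalue_experiment(pipeline, seed=0)
    row = rep.table.iloc[0]
    print(f"{pipeline:>22}: n={row.n_peptides}  KS={row.ks_statistic:.4f}  "
          f"KS p={row.ks_p:.3g}  trends removed={row.n_trends_removed}")
print("\nuniform p-values (KS p above the test level) mean the pipeline")
print("neither fabricates nor hides group differences on null data;")
print("omitting re-inflation leaves the tests slightly anti-conservative.")
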