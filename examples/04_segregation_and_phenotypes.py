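"""Segregation and phenotype statistics.

First the F2 segregation check: 15 phenotype-positive plants among 69
F2s is consistent with a 1:3 recessive single-locus ratio. Then a
two-group phenotype comparison with the exact Wilcoxon rank-sum test
(glume lengths in mm, n = 6 per genotype).
"""
from oatmap import segregation_chisq, summary_table, wilcoxon_rank_sum

seg = segregation_chisq(15, 69, ratio=(1, 3))
print(f"segregation: chi2({seg.df}, N = {seg.n_total}) = {seg.statistic:.2f}, "
      f"P = {seg.pvalue:.2f}  -> consistent with 1:3 (recessive, single locus)")

wild_type = [21.0, 22.3, 21.6, 20.9, 22.0, 21.8]
mutant = [10.4, 11.1, 10.8, 11.4, 10.6, 10.9]
summary, pvalues = summary_table({"wild_type": wild_type, "mutant": mutant})
print("\nglume length (mm):")
print(summary.to_string(float_format=lambda v: f"{v:.2f}"))
res = wilcoxon_rank_sum(wild_type, mutant)
print(f"Wilcoxon rank sum ({res.method}): p = {res.pvalue:.4f} "
      f"(pairwise table p = {pvalues[('wild_type', 'mutant')]:.4f})")
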