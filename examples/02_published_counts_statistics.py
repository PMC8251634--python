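"""Dose-response statistics on the published duplex-sequencing counts.

Recomputes per-replicate mutant frequencies from the published counts
(mutant nucleotides / total duplex bases), summarizes each concentration
group, and runs the study's statistics: linear trend on concentration
and a one-tailed Dunnett comparison of each EMS group to the vehicle
control (on log10 frequencies, the scale on which the published
significance pattern reproduces).
"""

from duplexmut import group_mean_mf, wilson_interval
from duplexmut.datasets import duplex_study_table, mutant_frequency_endpoints
from duplexmut.dose_response import dunnett_test, linear_trend

df = duplex_study_table()
print("group means (x1e-7):")
for conc, sub in df.groupby("concentration"):
    mfs = (sub["mutants"] / sub["duplex_bases"]).tolist()
    mean, sd = group_mean_mf(mfs)
    lo, hi = wilson_interval(int(sub["mutants"].sum()),
                             int(sub["duplex_bases"].sum()))
    print(f"  {conc:>6.2f} ug/mL: mean {mean * 1e7:5.2f} +/- {sd * 1e7:4.2f}"
          f"  (pooled 95% Wilson CI {lo * 1e7:.2f}-{hi * 1e7:.2f})")

table = mutant_frequency_endpoints()
trend = linear_trend(table, on="means")
print(f"\nlinear trend on group means: slope {trend.slope:.4f}, "
      f"p = {trend.p_value:.4f}")

res = dunnett_test(table, alternative="greater", seed=1, log=True)
print(f"one-tailed Dunnett (log10 scale), critical value "
      f"{res.critical_value:.3f}:")
for cmp in res.comparisons:
    mark = "*" if cmp.significant else " "
    print(f"  {cmp.concentration:>6.2f} ug/mL: t = {cmp.t_statistic:5.2f}, "
          f"adj. p = {cmp.adjusted_p:.4f} {mark}")
print("\n'*' marks groups with a significant mutant-frequency increase")
print("over the vehicle control at alpha = 0.05.")
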