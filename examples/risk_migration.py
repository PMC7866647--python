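"""Risk migration: how many patients change level under the combined score.

Scores a simulated cohort and cross-tabulates the IPSS-R category against
the MIPSS-R category, counting who moved down, stayed, or moved up.
"""

from mipssr import SimConfig, compare_stratifications, score_cohort, simulate_cohort

cohort = score_cohort(simulate_cohort(SimConfig(n=500, seed=11)))
table = compare_stratifications(cohort["ipssr_category"], cohort["mipssr_category"])

print(f"n={table.n}: {table.decreased} decreased ({table.pct_decreased}%), "
      f"{table.unchanged} unchanged, {table.elevated} elevated ({table.pct_elevated}%)")
print(f"risk level changes for {table.pct_changed}% of patients")
print(table.crosstab)
# Rows are the IPSS-R assignment, columns the MIPSS-R one; off-diagonal
# counts are patients whose treatment intensity guidance would change.
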