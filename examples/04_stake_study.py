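"""Known-population stake transect: why full independence under-estimates.

Simulates repeated double-observer surveys of 150 stakes with stake-level
heterogeneity in both detectability and visibility range, then compares
single-observer CDS, full-independence MRDS and point-independence MRDS
against the known truth.
"""

from apexds.bench import stake_ordering_experiment

res = stake_ordering_experiment(replicates=100, seed=1)

print(f"true population          : {res['true_n']}")
print(f"single-observer CDS mean : {res['mean_cds']:6.1f} "
      f"({res['bias_cds_pct']:+.1f}%)")
print(f"full independence mean   : {res['mean_fi']:6.1f} "
      f"({res['bias_fi_pct']:+.1f}%)")
print(f"point independence mean  : {res['mean_pi']:6.1f} "
      f"({res['bias_pi_pct']:+.1f}%)")
# CDS misses the ~20% of stakes that are hard for everyone (its certain-
# detection assumption fails); full independence is worse because shared
# heterogeneity inflates its mark-recapture probabilities; point
# independence, which only trusts the mark-recapture model on the line,
# lands within a few percent of the truth.
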