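"""Relative bias of CDS against MRDS on five published Alaskan bear surveys.

Recomputes the relative-bias column of the published survey table from the
printed abundance estimates: what ignoring mark-recapture data and
covariates costs, survey by survey.
"""

from apexds.bench import published_bias_table

t = published_bias_table()
cols = ["survey", "cds_2pn_estimate", "mrds_2pn_estimate",
        "relative_bias_pct", "apex_m", "mean_mr_p", "hn_truncation_pct"]
print(t[cols].to_string(index=False))
print()
print(f"bias range: {t['relative_bias_pct'].min():.2f}% to "
      f"{t['relative_bias_pct'].max():.2f}%")
# Every survey: the conventional estimate sits 17-21% below the MRDS
# reference, because apex detection is 0.83-0.95, not 1 - and a half-normal
# analysis would additionally discard 12-27% of detections below the apex.
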