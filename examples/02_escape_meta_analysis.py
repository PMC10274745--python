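"""Harmonize five allelic-ratio study dialects into escape/subject calls.

Simulates the five study formats (per-gene summaries, precomputed adjusted
p-values, single-cell active-X fractions, skew-adjusted bulk ratios, and
per-sample bulk ratios) for 500 X-linked genes of which 20% truly escape
X-inactivation, runs each dialect's caller, combines the verdicts, and
scores the final three-way classification against the simulated truth.
"""

import xydosage as xd
from xydosage.escape import ESCAPE, SUBJECT

# the published per-sample escape threshold corresponds to a cell whose
# active-X allele carries 95% of reads:
print(f"AR at 95% active-X fraction: {xd.ar_from_xa_fraction(0.95):.4f}")
print(f"baseline AR at skewing coefficient 0.8: {xd.baseline_ar(0.8):.2f}")

tables, truth = xd.simulate_allelic_studies(xd.SimAllelicConfig(seed=7))
calls = xd.classify_escape(tables)
merged = calls.join(truth)

print(merged["final"].value_counts().to_string())
called = merged[merged["final"].isin([ESCAPE, SUBJECT])]
tp = ((called["final"] == ESCAPE) & (called["truth"] == "escape")).sum()
fn = ((called["final"] != ESCAPE) & (called["truth"] == "escape")).sum()
tn = ((called["final"] == SUBJECT) & (called["truth"] == "subject")).sum()
fp = ((called["final"] == ESCAPE) & (called["truth"] == "subject")).sum()
print(f"sensitivity {tp / (tp + fn):.3f}, specificity {tn / (tn + fp):.3f}")
# Sensitivity is the fraction of true escape genes recovered; specificity
# the fraction of silenced ("subject", i.e. Xa-expressed) genes kept out of
# the escape set by the majority-plus-evidence combining rule.
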