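#!/usr/bin/env python
"""Variance-gated comparisons of every published summary variable.

Works directly from the printed group summaries (n = 3, mean, SD per
group): F-test gate, then Student or Welch, two-sided at alpha = 0.05.
Writes results/comparisons_published.csv and prints which variables
separate the defective from the non-defective cheeses.
"""

from pathlib import Path

import pandas as pd

from caseoscan.reference import REFERENCE_SUMMARIES, reference_groups
from caseoscan.stats import compare_groups

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for var in REFERENCE_SUMMARIES.variable.unique():
        ndc, dc = reference_groups(var)
        res = compare_groups(ndc, dc)
        rows.append(
            {
                "variable": var,
                "ndc_mean": ndc.mean, "ndc_sd": ndc.sd,
                "dc_mean": dc.mean, "dc_sd": dc.sd,
                "f_ratio": res.f_ratio, "f_p": res.f_p, "test_used": res.test_used,
                "t_stat": res.t_stat, "df": res.df, "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    df = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "comparisons_published.csv", index=False)

    sig = df[df.significant]
    print("significant at alpha = 0.05:")
    for r in sig.itertuples():
        print(f"  {r.variable}: {r.test_used}, p = {r.p_value:.4f}")
    print("\nborderline (0.05 <= p < 0.10):")
    for r in df[(~df.significant) & (df.p_value < 0.10)].itertuples():
        print(f"  {r.variable}: {r.test_used}, p = {r.p_value:.4f}")
    print(f"\nwrote {out / 'comparisons_published.csv'} ({len(df)} variables)")


if __name__ == "__main__":
    main()
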