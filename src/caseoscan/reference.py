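"""Published summary statistics of the 20-month cheese study.

Group means ± SD (n = 3 per group) for the non-defective (NDC) and
defective (DC) cheeses: NMR proton populations, microbial plate counts,
moisture, Young's modulus and the casein-fragment ratios.  These printed
summaries are the inputs to the variance-gated comparison scheme, and the
NDC relaxometry row doubles as the parameter set for synthetic CPMG
benchmarks.

The population-A standard deviation was published only as a bound
("< 0.01"); it is stored here as 0.009.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_SUMMARIES", "TABLE1_OPENINGS", "reference_groups"]

_ROWS = [
    # variable, group, n, mean, sd
    ("moisture_pct", "NDC", 3, 31.57, 0.30),
    ("moisture_pct", "DC", 3, 32.19, 0.28),
    ("young_modulus_MPa", "NDC", 3, 7.87, 1.72),
    ("young_modulus_MPa", "DC", 3, 7.55, 0.28),
    # proton populations: relative abundance (%) and T2 (ms)
    ("pop_A_pct", "NDC", 3, 5.44, 0.009),
    ("pop_A_pct", "DC", 3, 5.32, 0.08),
    ("pop_B_pct", "NDC", 3, 55.06, 0.08),
    ("pop_B_pct", "DC", 3, 54.55, 1.01),
    ("pop_C_pct", "NDC", 3, 23.58, 0.05),
    ("pop_C_pct", "DC", 3, 23.71, 0.79),
    ("pop_D_pct", "NDC", 3, 15.92, 0.04),
    ("pop_D_pct", "DC", 3, 16.42, 0.48),
    ("t2A_ms", "NDC", 3, 1.55, 0.12),
    ("t2A_ms", "DC", 3, 1.62, 0.19),
    ("t2B_ms", "NDC", 3, 10.78, 0.05),
    ("t2B_ms", "DC", 3, 11.13, 0.19),
    ("t2C_ms", "NDC", 3, 51.10, 1.37),
    ("t2C_ms", "DC", 3, 54.07, 2.16),
    ("t2D_ms", "NDC", 3, 170.79, 5.68),
    ("t2D_ms", "DC", 3, 180.54, 1.79),
    # plate counts, log CFU/mL
    ("lactobacilli_logcfu", "NDC", 3, 4.36, 0.30),
    ("lactobacilli_logcfu", "DC", 3, 3.52, 0.48),
    ("total_mesophilic_logcfu", "NDC", 3, 4.86, 0.14),
    ("total_mesophilic_logcfu", "DC", 3, 3.87, 0.41),
    ("yeasts_moulds_logcfu", "NDC", 3, 3.80, 0.73),
    ("yeasts_moulds_logcfu", "DC", 3, 4.10, 0.10),
    ("propionibacteria_logcfu", "NDC", 3, 4.19, 0.33),
    ("propionibacteria_logcfu", "DC", 3, 4.00, 0.97),
    # casein-fragment ratios (corrected-area ratios)
    ("as1I_over_as1", "NDC", 3, 0.38, 0.04),
    ("as1I_over_as1", "DC", 3, 0.29, 0.12),
    ("as_f1_23_over_as1plus0", "NDC", 3, 0.19, 0.05),
    ("as_f1_23_over_as1plus0", "DC", 3, 0.13, 0.01),
    ("as1PL_over_as1", "NDC", 3, 0.68, 0.20),
    ("as1PL_over_as1", "DC", 3, 0.56, 0.06),
    ("gamma_over_beta", "NDC", 3, 4.38, 1.45),
    ("gamma_over_beta", "DC", 3, 3.55, 0.58),
]

REFERENCE_SUMMARIES = pd.DataFrame(_ROWS, columns=["variable", "group", "n", "mean", "sd"])

#: published opening morphometry of the defective cheeses (group mean, SD)
TABLE1_OPENINGS = {
    "min_mm2": (0.39, 0.03),
    "d25_mm2": (0.71, 0.13),
    "d50_mm2": (1.31, 0.25),
    "d75_mm2": (3.48, 1.83),
    "max_mm2": (36.45, 12.37),
    "mean_mm2": (3.92, 1.10),
    "porosity_pct": (0.26, 0.10),
    "eye_fraction_pct": (75.0, None),
}


def reference_groups(variable: str):
    """(NDC, DC) GroupSummary pair for one reference variable."""
    from .stats import GroupSummary

    sub = REFERENCE_SUMMARIES[REFERENCE_SUMMARIES.variable == variable]
    if sub.empty:
        raise KeyError(f"unknown reference variable: {variable}")
    out = {}
    for r in sub.itertuples():
        out[r.group] = GroupSummary(
            label=r.group, n=int(r.n), mean=float(r.mean), sd=float(r.sd), variable=variable
        )
    return out["NDC"], out["DC"]
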