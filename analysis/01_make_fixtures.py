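#!/usr/bin/env python
"""Generate the synthetic two-group study (NDC vs DC, 3 replicates each).

Replicate-level truth is drawn around the published group means with the
published between-replicate SDs (affinely matched, so each group of three
hits its mean +- SD exactly), then rendered into raw fixtures: slice scans,
CPMG decays, penetration curves and CZE peak tables.  Raw fixtures and the
study config land under scratch/fixtures/ (they are bulky); everything
downstream reads them from there.

Run from the repository root:  python analysis/01_make_fixtures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from caseoscan import io, synthetic
from caseoscan.reference import REFERENCE_SUMMARIES

ROOT = Path(__file__).resolve().parents[1]
FIXDIR = ROOT / "scratch" / "fixtures"
SEED = 20
N_REP = 3


def replicate_values(variable: str, group: str, seed: int) -> np.ndarray:
    sel = (REFERENCE_SUMMARIES.variable == variable) & (REFERENCE_SUMMARIES.group == group)
    row = REFERENCE_SUMMARIES[sel].iloc[0]
    x, _ = synthetic.make_group_samples(row["mean"], row["sd"], N_REP, seed=seed, exact=True)
    return x


def main() -> None:
    FIXDIR.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    assays: dict = {"imaging": {}, "relaxometry": {}, "texture": {}, "peaks": {}}

    for grp in ("NDC", "DC"):
        for key in assays:
            assays[key][grp] = []
        # per-replicate planted parameters
        pops = {
            lab: (
                replicate_values(f"pop_{lab}_pct", grp, seed=SEED + ord(lab)),
                replicate_values(f"t2{lab}_ms", grp, seed=SEED + 50 + ord(lab)),
            )
            for lab in "ABCD"
        }
        moduli = replicate_values("young_modulus_MPa", grp, seed=SEED + 7)
        ratio_reps = {
            name: replicate_values(name, grp, seed=SEED + 11 + k)
            for k, name in enumerate(
                ("as1I_over_as1", "as_f1_23_over_as1plus0", "as1PL_over_as1", "gamma_over_beta")
            )
        }
        for rep in range(N_REP):
            tag = f"{grp.lower()}_{rep + 1}"
            # CPMG decay: abundances renormalised to 100 within each replicate
            pcts = np.array([pops[lab][0][rep] for lab in "ABCD"])
            pcts = 100.0 * pcts / pcts.sum()
            t2s = [pops[lab][1][rep] for lab in "ABCD"]
            decay, _ = synthetic.make_cpmg_decay(
                list(zip(pcts, t2s)), snr=1000.0, seed=int(rng.integers(2**31))
            )
            dpath = FIXDIR / f"{tag}_decay.csv"
            io.write_decay_csv(decay, dpath)
            assays["relaxometry"][grp].append(str(dpath))

            # penetration curve
            curve, _ = synthetic.make_penetration_curve(
                E_MPa=float(moduli[rep]), noise_rel=0.01, seed=int(rng.integers(2**31))
            )
            cpath = FIXDIR / f"{tag}_curve.csv"
            pd.DataFrame(
                {"displacement_mm": curve.displacement_mm, "force_N": curve.force_N}
            ).to_csv(cpath, index=False)
            assays["texture"][grp].append(str(cpath))

            # CZE peak table at this replicate's planted ratios
            ratios = {name: float(vals[rep]) for name, vals in ratio_reps.items()}
            peaks, _ = synthetic.make_peak_table(ratios, seed=int(rng.integers(2**31)))
            ppath = FIXDIR / f"{tag}_peaks.csv"
            pd.DataFrame(
                [{"peak_id": p.peak_id, "raw_area": p.raw_area, "migration_time": p.migration_time}
                 for p in peaks]
            ).to_csv(ppath, index=False)
            assays["peaks"][grp].append(str(ppath))

            # slice scans: only the defective cheeses have openings
            if grp == "DC":
                img, truth = synthetic.porosity_fixture(
                    porosity_pct=0.26, seed=int(rng.integers(2**31))
                )
            else:
                img, truth = synthetic.make_slice_image(
                    section_mm=(100.0, 100.0), openings=[], seed=int(rng.integers(2**31))
                )
            ipath = FIXDIR / f"{tag}_slice.png"
            Image.fromarray((img.pixels * 255).astype(np.uint8)).save(ipath)
            assays["imaging"][grp].append(str(ipath))

    # published moisture and plate counts enter as external summaries
    ext = REFERENCE_SUMMARIES[
        REFERENCE_SUMMARIES.variable.isin(
            ["moisture_pct", "lactobacilli_logcfu", "total_mesophilic_logcfu",
             "yeasts_moulds_logcfu", "propionibacteria_logcfu"]
        )
    ]
    spath = FIXDIR / "external_summaries.csv"
    ext.to_csv(spath, index=False)
    assays["summaries"] = str(spath)

    config = {"groups": ["NDC", "DC"], "assays": assays, "seed": SEED}
    with open(FIXDIR / "study.yml", "w") as fh:
        yaml.safe_dump(config, fh)
    n_files = sum(len(v) for a in assays.values() if isinstance(a, dict) for v in a.values())
    print(f"wrote {n_files} replicate fixtures + study.yml under {FIXDIR}")


if __name__ == "__main__":
    main()
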