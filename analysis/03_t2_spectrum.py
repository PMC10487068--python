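#!/usr/bin/env python
"""Quasi-continuous T2 spectra of the two cheese groups.

Simulates the benchmark CPMG acquisition (tau 80 us, 30,000 points,
SNR 1000) for the non-defective and defective population parameters,
inverts each decay to a regularised T2 distribution, and reports the
resolved modes and valley-integrated population areas.  Writes
results/t2_spectra.csv (grid + densities) and results/t2_modes.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from caseoscan import synthetic
from caseoscan.relaxometry import invert_t2_spectrum, population_areas

ROOT = Path(__file__).resolve().parents[1]
SEED = 20


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    spectra = {}
    rows = []
    for grp, pops in (("NDC", synthetic.NDC_POPULATIONS), ("DC", synthetic.DC_POPULATIONS)):
        decay, truth = synthetic.make_cpmg_decay(pops, snr=1000.0, seed=SEED)
        spec = invert_t2_spectrum(decay)
        spectra[grp] = spec
        modes = spec.modes_ms()
        areas = population_areas(spec)
        print(f"{grp}: {modes.size} modes at {np.round(modes, 2)} ms")
        print(f"     planted T2  {[p.t2_ms for p in pops]} ms")
        print(f"     areas {np.round(areas, 2)} % (planted {[p.abundance_pct for p in pops]})")
        for label, mode, area in zip("ABCD", modes, areas):
            rows.append({"group": grp, "population": label, "mode_t2_ms": float(mode),
                         "area_pct": float(area)})
    grid = spectra["NDC"].t2_grid
    pd.DataFrame(
        {"t2_ms": grid, "density_NDC": spectra["NDC"].density, "density_DC": spectra["DC"].density}
    ).to_csv(out / "t2_spectra.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "t2_modes.csv", index=False)
    print(f"\nwrote {out / 't2_spectra.csv'} and {out / 't2_modes.csv'}")


if __name__ == "__main__":
    main()
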