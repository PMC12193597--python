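"""Optical-property accuracy on a grid of tissue-mimicking calibration phantoms.

Simulates 25 homogeneous phantoms spanning absorption 0.5-1.5 cm^-1 and
reduced scattering 10-30 cm^-1 at 490 and 590 nm, degrades the raw
structured-illumination images with 1% multiplicative noise, calibrates
against the known (mua=1.0, musp=20) reference phantom and inverts per
pixel over five spatial frequencies (0-2.0 cm^-1).

Writes results/phantom_grid.csv (per-phantom recovered values and errors)
and results/phantom_summary.json.
"""

import json
from pathlib import Path

from sfdiq.experiments import phantom_grid_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    res = phantom_grid_experiment(seed=seed)
    res.table.to_csv(OUT / "phantom_grid.csv", index=False)
    summary = {
        "mean_abs_pct_err_mua_pixelwise": round(res.mean_abs_pct_err_mua, 3),
        "max_pct_err_both_params_phantomwise": round(res.max_pct_err_both, 3),
        "n_phantoms": int(len(res.table) // 2),
        "n_pixels_total": res.n_pixels_total,
        "seed": seed,
    }
    (OUT / "phantom_summary.json").write_text(json.dumps(summary, indent=1))
    print("Phantom-grid accuracy (1% multiplicative noise, 64x64 px):")
    print(f"  mean |%err| in mua over all phantoms and pixels: "
          f"{res.mean_abs_pct_err_mua:.2f}%")
    print(f"  max phantom-level |%err| over both parameters:   "
          f"{res.max_pct_err_both:.2f}%")
    print(f"  tables -> {OUT / 'phantom_grid.csv'}")


if __name__ == "__main__":
    main()
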