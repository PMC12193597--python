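"""Tumor/periphery fluorescence contrast: inversion by attenuation, restoration by correction.

Builds an elliptical tumor scene with absorption 40% and reduced scattering
15% above the periphery and a true photosensitizer concentration ratio of
1.33 (0.24 vs 0.18 ug/mL).  Runs the full pipeline and reports the
tumor/periphery fluorescence ratio before and after attenuation correction:
the raw ratio drops below 1 (the darker, more absorbing tumor *looks*
dimmer despite carrying more drug) and the corrected ratio recovers the
true contrast.

Writes results/tumor_contrast.json.
"""

import json
from pathlib import Path

from sfdiq.experiments import tumor_contrast_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    res = tumor_contrast_experiment(seed=seed, noise=None)
    report = {k: round(v, 4) for k, v in res.items() if isinstance(v, float)}
    report["seed"] = seed
    (OUT / "tumor_contrast.json").write_text(json.dumps(report, indent=1))
    print("Tumor/periphery contrast (noise-free scene):")
    print(f"  raw fluorescence ratio:       {res['raw_ratio']:.3f}  (< 1: inverted)")
    print(f"  corrected concentration ratio: {res['corrected_ratio']:.3f}  "
          f"(true {res['true_ratio']:.3f})")
    print(f"  tumor    {res['tumor_concentration_ugml']:.3f} ug/mL")
    print(f"  periphery {res['periphery_concentration_ugml']:.3f} ug/mL")
    print(f"  recovered property elevation: mua +{res['recovered_mua_elevation_pct']:.1f}%, "
          f"musp +{res['recovered_musp_elevation_pct']:.1f}%")
    print(f"  report -> {OUT / 'tumor_contrast.json'}")


if __name__ == "__main__":
    main()
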