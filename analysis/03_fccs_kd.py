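#!/usr/bin/env python
"""Ligand-receptor dissociation constant from cross-correlation amplitudes.

Forward-evaluates the background-corrected amplitude equations on the
concentration fixture (free ligand 40 nM, free receptor 70 nM, bound
25 nM at V_eff = 0.5 fL), inverts them numerically, and applies mass
action; then aggregates 23 noisy synthetic measurements around the same
truth by zero-intercept regression.  Writes results/fccs_kd.json.
"""

import json
from pathlib import Path

from fcskit.experiments import fccs_kd_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    res = fccs_kd_experiment(seed=seed)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "fccs_kd.json").write_text(json.dumps(res, indent=2))
    a = res["amplitudes"]
    print(
        f"amplitudes: G_G(0)={a['G_G0']:.4f}  G_R(0)={a['G_R0']:.4f}  "
        f"G_x(0)={a['G_x0']:.5f}"
    )
    c = res["recovered_nM"]
    print(f"inverted concentrations: Cg={c['Cg']:.1f}  Cr={c['Cr']:.1f}  "
          f"Cgr={c['Cgr']:.1f} nM")
    print(
        f"fixture Kd = {res['Kd_nM']:.1f} nM (published in vivo value "
        f"112 ± 15 nM); aggregate over {res['n_measurements']} noisy "
        f"measurements: {res['aggregate_Kd_nM']:.1f} nM, "
        f"R² = {res['aggregate_R2']:.2f}"
    )


if __name__ == "__main__":
    main()
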