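#!/usr/bin/env python
"""Global (ensemble) diffusion from FRAP recovery fixtures.

Simulates noiseless double-exponential recoveries for the ligand
(tau_fast 300 s, bleach radius 24.5 µm) and the secreted control
(tau_fast 30 s, radius 39.5 µm), fits them, and converts the fast time
constant to the apparent global diffusion coefficient D = r²/(4 tau).
Writes results/frap_recovery.csv and reports the local-vs-global contrast
that motivates hindered extracellular transport.
"""

from pathlib import Path

import pandas as pd

from fcskit.experiments import frap_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"

D_LOCAL = {"wnt3": 27.6, "secegfp": 57.9}  # µm²/s, fluctuation-based


def main() -> None:
    rows = []
    for name in ("wnt3", "secegfp"):
        res = frap_experiment(name)
        res["D_local_um2_s"] = D_LOCAL[name]
        res["local_over_global"] = res["D_local_um2_s"] / res["D_global_um2_s"]
        rows.append(res)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "frap_recovery.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    wnt3, sec = rows
    print(
        f"\nligand: D_global = {wnt3['D_global_um2_s']:.2f} µm²/s, a factor "
        f"{wnt3['local_over_global']:.0f} below its local D — far beyond the "
        f"factor {sec['local_over_global']:.1f} tortuosity alone costs the "
        "inert control; the gap is the signature of transient HSPG and "
        "receptor binding."
    )


if __name__ == "__main__":
    main()
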