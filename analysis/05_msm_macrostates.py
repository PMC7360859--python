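"""Markov-state model over tICA space: k-means microstates, reversible MSM
at a 10 ns lag, implied-timescale table, Chapman-Kolmogorov validation,
PCCA+ macrostates and their mean first-passage times. Writes all model
tables to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from tcrmsm import clustering, msm  # noqa: E402

RESULTS = ROOT / "results"
N_MACRO = 2


def main() -> None:
    proj = pd.read_csv(RESULTS / "04_tica_projections.csv").to_numpy()
    dtraj, centers, _ = clustering.kmeans(proj, 100, seed=515)
    np.savetxt(RESULTS / "05_kmeans_centers.csv", centers, delimiter=",")

    models = [msm.estimate_msm(dtraj, lag, 1.0) for lag in (5, 10, 20, 40)]
    msm.implied_timescales(models, k=3).to_csv(RESULTS / "05_implied_timescales.csv")

    model = models[1]                         # 10 ns lag
    ck = msm.chapman_kolmogorov(dtraj, model, N_MACRO, seed=516,
                                frame_interval=1.0)
    ck.records.to_csv(RESULTS / "05_ck_report.csv", index=False)

    macro = msm.pcca_plus(model, N_MACRO)
    pd.DataFrame({
        "microstate": model.active_set,
        "macrostate": macro.crisp_assignment,
        "stationary": model.stationary,
    }).to_csv(RESULTS / "05_microstate_table.csv", index=False)
    pd.DataFrame(macro.mfpt_matrix,
                 columns=[f"to_{a}" for a in range(N_MACRO)]
                 ).to_csv(RESULTS / "05_mfpt_ns.csv", index=False)

    pos = {s: i for i, s in enumerate(model.active_set)}
    frame_macro = np.array([macro.crisp_assignment[pos[m]] if m in pos else -1
                            for m in dtraj.states])
    pd.DataFrame({"frame": np.arange(frame_macro.size),
                  "macrostate": frame_macro}
                 ).to_csv(RESULTS / "05_frame_macrostates.csv", index=False)

    print(f"{model.n_states} connected microstates; "
          f"slowest timescale {model.timescales(1)[0]:.1f} ns")
    print(f"macrostate populations {np.round(macro.macro_stationary, 3).tolist()}")
    print(f"CK pass fraction {ck.pass_fraction():.2f}")


if __name__ == "__main__":
    main()
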