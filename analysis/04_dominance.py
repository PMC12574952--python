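"""Dominance decomposition of discriminability variance over time.

At every window center the discriminability score is regressed on ΔSD and
ΔAmplitude; total dominance splits the full R² between the two predictors,
showing which of them carries the explained variance in which time window.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neurovar.cohort import cohort_tracksets, delta_tracks
from neurovar.discrim import discriminability_scores
from neurovar.dominance import dominance_track
from neurovar.io import read_cohort, read_ratings
from neurovar.plotting import plot_dominance

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    ratings = read_ratings(ROOT / "cohort" / "ratings.tsv")
    scores = discriminability_scores(ratings)
    var_d = delta_tracks(cohort_tracksets(cohort, "tempSD"))
    amp_d = delta_tracks(cohort_tracksets(cohort, "amplitude"))
    dom = dominance_track(scores, var_d, amp_d)
    pd.DataFrame(
        {"time_ms": dom.times, "r2_full": dom.r2_full,
         "td_var": dom.td_var, "td_amp": dom.td_amp}
    ).to_csv(ROOT / "dominance.tsv", sep="\t", index=False)
    ax = plot_dominance(dom, title="total dominance of ΔSD vs ΔAmplitude")
    ax.figure.savefig(ROOT / "dominance.png", dpi=120)

    peak = int(np.argmax(dom.r2_full))
    print(f"peak R²_full = {dom.r2_full[peak]:.3f} at {dom.times[peak]:.0f} ms")
    early = (dom.times > 100) & (dom.times < 300)
    late = (dom.times > 300) & (dom.times < 500)
    print(f"mean td_var 100-300 ms = {dom.td_var[early].mean():.3f}, "
          f"td_amp = {dom.td_amp[early].mean():.3f}")
    print(f"mean td_var 300-500 ms = {dom.td_var[late].mean():.3f}, "
          f"td_amp = {dom.td_amp[late].mean():.3f}")


if __name__ == "__main__":
    main()
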