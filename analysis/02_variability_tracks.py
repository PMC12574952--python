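"""Windowed variability and amplitude tracks of the simulated cohort.

Computes per-subject sliding-window (100 ms, 1 ms step) temporal-SD and
mean-amplitude tracks per intensity condition, their high-low differences,
and writes condition averages plus the subject-mean ΔSD track (whose
post-stimulus peak defines the ROI used downstream).
"""

from pathlib import Path

from neurovar.cohort import cohort_tracksets, delta_tracks, grand_average, tracks_frame
from neurovar.io import read_cohort
from neurovar.variability import peak_roi

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    for metric, fname in (("tempSD", "delta_sd"), ("amplitude", "delta_amplitude")):
        deltas = delta_tracks(cohort_tracksets(cohort, metric))
        tracks_frame(deltas).to_csv(ROOT / f"{fname}_tracks.tsv", sep="\t", index=False)
        ga = grand_average(deltas)
        if metric == "tempSD":
            lo, hi = peak_roi(ga)
            print(f"subject-mean ΔSD peaks at {(lo + hi) / 2:.0f} ms "
                  f"(ROI {lo:.0f}-{hi:.0f} ms)")
        tracks_frame([ga]).to_csv(ROOT / f"{fname}_grand_average.tsv", sep="\t", index=False)
    print(f"wrote tracks under {ROOT}")


if __name__ == "__main__":
    main()
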