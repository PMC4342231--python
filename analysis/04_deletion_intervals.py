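#!/usr/bin/env python
"""Deletion-interval brackets from the intactness matrix of 03, plus the
worked single-mutant example bracket, rendered as a text track.

Run analysis/03_amplicon_pipeline.py first; this script reads its outputs.
"""

from pathlib import Path

import yaml

from delstack import io as dio
from delstack.report import render_interval_track
from delstack.synteny_map import IntactnessProfile, infer_deletion_interval

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = dio.load_marker_panel()

    # the worked example: deleted 400 kb Up - 100 kb Down, intact at 700 Up / 200 Down
    calls = {}
    for m in panel:
        if -400 <= m.offset_kb <= 100:
            calls[m.gene_id] = "deleted"
        elif m.offset_kb in (-700, 200):
            calls[m.gene_id] = "intact"
    worked = infer_deletion_interval(
        IntactnessProfile("worked-example", "A", calls), panel
    )
    print(f"worked example bracket: [{worked.min_size:.0f}, {worked.max_size:.0f}] kb")

    matrix_path = OUT / "intactness_matrix.tsv"
    if not matrix_path.exists():
        raise SystemExit("run analysis/03_amplicon_pipeline.py first")
    matrix = dio.read_calls_matrix(str(matrix_path))
    with open(OUT / "mutant_truth.yaml") as fh:
        truth = yaml.safe_load(fh)

    anchor = panel.anchor.gene_id
    intervals = {}
    for (sample, sub), gene_calls in matrix.items():
        if gene_calls.get(anchor) != "deleted":
            continue
        profile = IntactnessProfile(sample, sub, gene_calls)
        intervals[(sample, sub)] = infer_deletion_interval(profile, panel)
    dio.write_intervals(intervals, str(OUT / "deletion_intervals.csv"))

    track = render_interval_track(intervals, panel)
    (OUT / "interval_track.txt").write_text(track + "\n")
    print(track)
    print("\nbracket vs truth:")
    for (sample, sub), iv in sorted(intervals.items()):
        t = truth[sample]["true_span_kb"]
        hi = "open" if iv.max_size is None else f"{iv.max_size:.0f}"
        ok = iv.min_size <= t and (iv.max_size is None or t <= iv.max_size)
        print(f"  {sample}:{sub}  true {t:7.1f} kb in [{iv.min_size:.0f}, {hi}] -> "
              f"{'contained' if ok else 'MISSED'}")


if __name__ == "__main__":
    main()
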