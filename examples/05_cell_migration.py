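"""Track-level motility metrics and a two-condition comparison.

Simulates persistent random walks for cells on plastic (noisy headings)
and on an ECM coating (more persistent, larger steps), then compares
speed and directionality index between the conditions.
"""

import pandas as pd

from ecmnet.cohort_io import TrackTable
from ecmnet.migration import compare_conditions, filter_tracks, table_metrics
from ecmnet.synthetic import SyntheticTrackSpec, generate_tracks

plastic = generate_tracks(SyntheticTrackSpec(
    n_tracks=120, angular_noise=1.2, step_scale=1.5, condition="plastic", seed=1))
ecm = generate_tracks(SyntheticTrackSpec(
    n_tracks=120, angular_noise=0.5, step_scale=2.0, condition="ecm", seed=2))
ecm_data = ecm.data.assign(track_id="ECM_" + ecm.data["track_id"])
tracks = TrackTable(pd.concat([plastic.data, ecm_data], ignore_index=True))

tracks = filter_tracks(tracks, min_points=5)
metrics = table_metrics(tracks)
print(metrics.groupby("condition")[["speed", "directionality_index"]]
      .median().round(3).to_string())

for value in ("speed", "directionality_index"):
    report = compare_conditions(metrics, value=value)
    print(f"{value}: Mann-Whitney U = {report['statistic']:.0f}, "
          f"p = {report['p_value']:.2e}")
# Higher median speed (um/h) and directionality index (net/total path, 1 =
# perfectly straight) on the ECM coating mirror the pro-migratory effect
# the assay is designed to detect.
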