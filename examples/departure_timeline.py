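"""Departure-date uncertainty: known dates vs inclusive day windows.

With no receiving station near the capture site, most birds get a window of
possible departure days instead of an exact date. Each bird spreads one unit
of weight uniformly over its window; summing across birds gives a departure
timeline whose total mass equals the number of birds.
"""

import pandas as pd

from rufatrack import departure_timeline, estimate_departure, weighted_median_date
from rufatrack.model import DetectionBout
from rufatrack.simulate import BASE_STATIONS, CAPTURE_LAT, CAPTURE_LON, make_regions


def bout(tag, station, when):
    t = pd.Timestamp(when)
    return DetectionBout(tag_id=tag, station_id=station, start=t, end=t, n_detections=3)


def deployment(tag, when):
    return pd.Series({"tag_id": tag, "deploy_time_utc": pd.Timestamp(when),
                      "deploy_lat": CAPTURE_LAT, "deploy_lon": CAPTURE_LON})


regions = make_regions()
coords = dict(BASE_STATIONS)

# bird A: first seen at an inland South Carolina station -> known date
est_a = estimate_departure([bout("A", "SC_INLAND", "2019-05-10T12:00:00Z")],
                           deployment("A", "2019-05-06T14:00:00Z"), regions,
                           station_coords=coords)
# bird B: first seen on the North Carolina coast 4 days after deployment
# -> five-day window, 0.2 per day
est_b = estimate_departure([bout("B", "NC_COAST", "2019-05-12T09:00:00Z")],
                           deployment("B", "2019-05-08T14:00:00Z"), regions,
                           station_coords=coords)

print(f"bird A: {est_a.kind} departure on {est_a.known_date}")
print(f"bird B: {est_b.kind} {est_b.window_start} .. {est_b.window_end}, "
      f"per-day weight {list(est_b.weights.values())[0]:.2f}")

timeline = departure_timeline([est_a, est_b])
print("\ndate        summed weight")
for d, w in timeline.items():
    print(f"{d}  {w:.2f}")
print(f"\ntotal mass = {sum(timeline.values()):.2f} (= number of birds)")
print(f"weighted median departure: {weighted_median_date(timeline)}")
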