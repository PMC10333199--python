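"""The stopover decision rules on hand-built detection bouts.

A stopover needs detections spanning > 4 h at one station (or > 6 h across
stations within 30 km of each other), at stations more than 50 km from the
tagging location. Thresholds are strict: exactly 4.0 h is not a stopover.
"""

import pandas as pd

from rufatrack import detect_stopovers
from rufatrack.model import DetectionBout

CAP = (32.54, -80.17)                     # tagging location
COORDS = {"FAR": (34.5, -80.17),          # ~220 km north
          "NEAR": (32.9, -80.17)}         # ~40 km north: inside the exclusion

deployment = pd.Series({"tag_id": "B1", "deploy_lat": CAP[0], "deploy_lon": CAP[1],
                        "deploy_time_utc": pd.Timestamp("2019-05-01T14:00:00Z")})
T0 = pd.Timestamp("2019-05-20T06:00:00Z")


def bout(station, start_h, end_h):
    return DetectionBout(tag_id="B1", station_id=station,
                         start=T0 + pd.Timedelta(hours=start_h),
                         end=T0 + pd.Timedelta(hours=end_h), n_detections=10)


for label, bouts in [
    ("4.5 h at a far station ", [bout("FAR", 0, 4.5)]),
    ("4.0 h exactly          ", [bout("FAR", 0, 4.0)]),
    ("10 h but only 40 km out", [bout("NEAR", 0, 10.0)]),
]:
    found = detect_stopovers(bouts, deployment, COORDS)
    if found:
        s = found[0]
        print(f"{label} -> stopover, {s.duration_h:.1f} h at {sorted(s.stations)}")
    else:
        print(f"{label} -> no stopover")
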