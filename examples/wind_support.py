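"""Tailwind support: sample a wind grid and project onto a flight bearing.

Tailwind is the component of the surface wind (u eastward, v northward,
1000 hPa) along the great-circle bearing from the departure station to the
arrival station: u*sin(beta) + v*cos(beta). Positive values assist flight;
any wind within 90 degrees of the direction of movement is a tailwind.
"""

import pandas as pd

from rufatrack import initial_bearing, sample_wind, simulate_wind, tailwind_support

wind = simulate_wind(seed=42)

# a northbound flight: inland South Carolina to Lake Erie
a = (33.95, -81.12)
b = (42.20, -80.10)
beta = initial_bearing(*a, *b)
when = pd.Timestamp("2019-05-16T08:30:00Z")   # nearest 6-h slice is used

u, v = sample_wind(wind, when, *a)            # bilinear at the departure point
tw = tailwind_support(u, v, beta)
print(f"bearing to destination: {beta:.1f} deg")
print(f"wind at departure: u = {u:+.1f} m/s east, v = {v:+.1f} m/s north")
print(f"tailwind component: {tw:+.1f} m/s -> "
      f"{'tailwind' if tw > 0 else 'headwind'} for this flight")

# a pure crosswind contributes nothing
print(f"\ncrosswind check (u=10, v=0, due north): "
      f"{tailwind_support(10.0, 0.0, 0.0):+.1f} m/s")
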