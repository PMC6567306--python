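"""Simulate one week of routine and render a day's pheromone maps.

Generates a synthetic motion-sensor log for a single occupant, runs the
preprocessing pipeline (OFF filtering, debouncing, place mapping), and
renders the 24 hourly 128x128 grayscale maps of the first day to PNG.
"""

import datetime as dt

from pheromap import (
    PheromoneParams,
    auto_intensity_cap,
    default_profile,
    generate_routine_log,
    hourly_counts,
    preprocess,
    render_day_images,
    standard_scenario,
)
from pheromap.pheromone import write_day_maps
from pheromap.simulate import scenario_mapping

profile = default_profile()
spec = standard_scenario(seed=1, n_days=7)
log = generate_routine_log(profile, spec)
placed, ledger = preprocess(log, scenario_mapping(profile, spec))
counts = hourly_counts(placed)

print("stage ledger:", ledger)
# parsed raw events vs events kept after OFF filtering and debouncing

cap = auto_intensity_cap(counts)
print(f"grayscale white point (99th pct of hourly counts): {cap:.1f} events/hour")

params = PheromoneParams()
images = render_day_images(counts[0], params, intensity_cap=cap)
write_day_maps(counts[0].day, images, "maps_example", montage=True)
print(f"wrote 24 hourly maps + montage for {counts[0].day} to maps_example/")
print("brightest pixel each hour:", [int(img.max()) for img in images])
# bright hours = high activity at some place; all-black hours = empty home or sleep elsewhere
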