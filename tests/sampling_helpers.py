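"""Shared helper for sampling tests: a single-month record bucket."""

from datetime import datetime, timedelta

from conftest import make_record


def month_bucket(n: int, year: int = 2022, month: int = 4):
    records = []
    for i in range(n):
        start = datetime(year, month, 1 + (i % 27), 9, 0) + timedelta(minutes=i)
        records.append(
            make_record(
                record_id=f"S{i:03d}",
                patient_key=f"Q{i:03d}",
                mission_start=start,
                on_scene_arrival=start + timedelta(minutes=10),
                scene_departure=start + timedelta(minutes=25),
            )
        )
    return {(year, month): records}
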