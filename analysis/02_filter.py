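"""Apply the filtering ladder (LC Z, on-land, 5 kph speed, -200 m depth) and
compute mean daily locations.

Reads results/sim/, writes results/filtered.csv and results/daily.csv.
"""

import pathlib

from gulftrack.argos import filter_fixes, mean_daily_locations, read_fixes, retained
from gulftrack.synthetic import build_habitat

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 7) -> None:
    habitat = build_habitat(seed=seed)
    fixes = read_fixes(ROOT / "sim" / "fixes.csv")
    flagged = filter_fixes(fixes, habitat)
    flagged.to_csv(ROOT / "filtered.csv", index=False)
    daily = mean_daily_locations(flagged)
    daily.to_csv(ROOT / "daily.csv", index=False)

    n = len(flagged)
    kept = len(retained(flagged))
    reasons = flagged[flagged.rejection_reason != ""].rejection_reason.value_counts()
    print(f"{n} fixes -> {kept} retained ({kept / n:.1%}); rejections: {reasons.to_dict()}")
    print(f"{len(daily)} mean daily locations")


if __name__ == "__main__":
    main()
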