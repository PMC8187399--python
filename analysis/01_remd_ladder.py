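"""Build the 20-replica geometric temperature ladder for a 300-800 K
effective range and its solute-tempering scaling factors.

Writes results/ladder.json and prints the rung table. With 20 replicas
at 400 ns each the campaign's aggregate sampling is 8 microseconds.
"""

import json
from pathlib import Path

import numpy as np

from confobs.remd import aggregate_time_us, geometric_ladder, scaling_factors

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ladder = geometric_ladder(300.0, 800.0, 20)
    lam = scaling_factors(ladder)
    temps = ladder.rounded_temperatures()

    print("rung  T (K)      lambda")
    for i, (t, s) in enumerate(zip(temps, lam)):
        print(f"{i:4d}  {t:8.3f}  {s:.6f}")
    total = aggregate_time_us(20, 400.0)
    print(f"\naggregate sampling: 20 replicas x 400 ns = {total:.1f} us")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ladder.json").write_text(json.dumps({
        "temperatures_K": temps.tolist(),
        "scaling_factors": np.round(lam, 6).tolist(),
        "aggregate_time_us": total,
    }, indent=2) + "\n")
    print(f"wrote {RESULTS / 'ladder.json'}")


if __name__ == "__main__":
    main()
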