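"""Sample-size computation for the paired cell-shedding endpoint.

Prior data: mean fold increase 41.3 with SD 60.4 over 9 patients.
Finds the smallest n giving 90% power for a one-tailed paired t-test at
alpha 0.05 (exact noncentral-t power), and prints the power curve around
the answer.
"""

import json
from pathlib import Path

from confobs.trial import TrialDesign, minimal_n, normal_approx_n, power_paired_t

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = TrialDesign(mean=41.3, sd=60.4, alpha=0.05, power=0.90, tails=1)
    n = minimal_n(design)

    print(f"effect size d = {design.effect_size:.4f}")
    print(f"normal approximation: n >= {normal_approx_n(design):.1f}")
    print("n    power")
    for k in range(max(2, n - 3), n + 3):
        marker = " <- minimal" if k == n else ""
        print(f"{k:3d}  {power_paired_t(design, k):.4f}{marker}")
    print(f"\nminimal per-group sample size: {n} patients")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "sample_size.json").write_text(json.dumps({
        "minimal_n": n,
        "power_at_n": power_paired_t(design, n),
        "power_at_n_minus_1": power_paired_t(design, n - 1),
        "normal_approx_n": normal_approx_n(design),
    }, indent=2) + "\n")
    print(f"wrote {RESULTS / 'sample_size.json'}")


if __name__ == "__main__":
    main()
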