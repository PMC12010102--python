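#!/usr/bin/env python
"""Step 3: mediation analysis with bootstrap confidence intervals.

Fits the three-regression mediation model (bullying -> negative affect ->
short-video addiction) on the scored cohort, full sample and split by
addiction class, with percentile bootstrap CIs. Writes results/tables/
mediation.csv and prints the decomposition.
"""

from pathlib import Path

import pandas as pd

from svamech.mediation import mediate, subgroup_mediate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
TABLES = ROOT / "results" / "tables"
SEED = 20251003
N_BOOT = 5000


def _row(label: str, res) -> dict:
    return {
        "sample": label, "n": res.n,
        "a": round(res.a, 4), "b": round(res.b, 4),
        "c_total": round(res.c, 4), "c_prime": round(res.cprime, 4),
        "indirect": round(res.indirect, 4),
        "ci_low": round(res.ci_low, 4), "ci_high": round(res.ci_high, 4),
        "prop_mediated_pct": round(res.prop_mediated, 2),
        "significant": res.significant,
    }


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    scored = pd.read_csv(SCRATCH / "scored.csv")

    full = mediate(scored["BV"], scored["NA"], scored["SVA"],
                   n_boot=N_BOOT, seed=SEED)
    rows = [_row("full", full)]
    print(f"full sample (n={full.n}): a={full.a:.3f} b={full.b:.3f} "
          f"c'={full.cprime:.3f} indirect={full.indirect:.3f} "
          f"95% CI [{full.ci_low:.3f}, {full.ci_high:.3f}] "
          f"({full.prop_mediated:.1f}% mediated)")

    sub = subgroup_mediate(scored, "BV", "NA", "SVA",
                           split="addiction_class", n_boot=N_BOOT, seed=SEED)
    for label, entry in sub.items():
        res = entry["mediation"]
        rows.append(_row(label, res))
        print(f"{label} (n={res.n}): indirect={res.indirect:.3f} "
              f"CI [{res.ci_low:.3f}, {res.ci_high:.3f}]")

    pd.DataFrame(rows).to_csv(TABLES / "mediation.csv", index=False)
    print(f"wrote {TABLES / 'mediation.csv'}")


if __name__ == "__main__":
    main()
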