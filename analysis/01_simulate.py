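#!/usr/bin/env python
"""Step 1: generate the synthetic study data.

Simulates a college-sized questionnaire cohort under the bullying ->
negative affect -> short-video-addiction structural model, plus a smaller
neuroimaging subsample with resting-state parcel time series in which two
parcels carry planted pattern coupling to the addiction item profile.

Bulky per-subject arrays go under scratch/ (binary, regenerable); later
steps read them from there. Summary tables land under results/.
"""

from pathlib import Path

import numpy as np

from svamech.psychometrics import DEFAULT_SCALES
from svamech.synthetic import (
    GenParams,
    NeuroGenParams,
    gen_questionnaire_cohort,
    gen_resting_parcels,
)
from svamech.alff import write_parcel_set

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
SEED = 20251002

N_COHORT = 1615
N_NEURO = 100
N_PARCELS = 200
PLANTED = (3, 40)  # parcels with pattern coupling to the addiction profile


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)

    table, truth = gen_questionnaire_cohort(
        GenParams(n_subjects=N_COHORT, seed=SEED))
    table.to_csv(SCRATCH / "questionnaire.csv", index=False)
    truth["latents"].to_csv(SCRATCH / "latents.csv", index=False)
    print(f"questionnaire cohort: {len(table)} subjects, "
          f"{table.shape[1]} columns -> {SCRATCH / 'questionnaire.csv'}")

    sub = table.head(N_NEURO)
    sva_items = list(DEFAULT_SCALES["SVA"].items)
    profile = sub[sva_items].to_numpy(float)
    pts, _ = gen_resting_parcels(
        NeuroGenParams(n_subjects=N_NEURO, n_parcels=N_PARCELS,
                       pattern_coupling_parcels=PLANTED,
                       pattern_strength=0.5, seed=SEED),
        trait=profile.sum(axis=1),
        item_profile=profile,
    )
    manifest = write_parcel_set(pts, SCRATCH / "parcels")
    np.save(SCRATCH / "neuro_subject_rows.npy", np.arange(N_NEURO))
    print(f"neural subsample: {N_NEURO} subjects x {N_PARCELS} parcels "
          f"-> {manifest}")


if __name__ == "__main__":
    main()
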