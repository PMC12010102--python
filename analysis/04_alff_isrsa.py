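#!/usr/bin/env python
"""Step 4: neural analyses - ALFF, trait association, and IS-RSA.

Reads the simulated resting-state parcel set, computes voxel-wise ALFF,
relates parcel-mean ALFF to the addiction score (Bonferroni-corrected),
and runs inter-subject representational similarity analysis between the
addiction item-profile RDM and per-parcel neural-pattern RDMs, with a
Mantel permutation follow-up on the top parcel.
"""

from pathlib import Path

import pandas as pd

from svamech.alff import alff_maps, parcel_mean_table, read_parcel_set
from svamech.association import parcel_association
from svamech.isrsa import behavioral_rdm, isrsa_map, mantel_permutation, neural_rdm
from svamech.psychometrics import DEFAULT_SCALES

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
TABLES = ROOT / "results" / "tables"
SEED = 20251004


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    pts = read_parcel_set(SCRATCH / "parcels")
    scored = pd.read_csv(SCRATCH / "scored.csv").head(pts.data.shape[0])
    items = pd.read_csv(SCRATCH / "questionnaire.csv").head(pts.data.shape[0])

    maps = alff_maps(pts)
    parcel_mean_table(maps).round(4).to_csv(SCRATCH / "alff_parcel_means.csv",
                                            index=False)

    assoc = parcel_association(maps, scored["SVA"].to_numpy(float),
                               correction="bonferroni")
    assoc.to_csv(TABLES / "alff_association.csv", index=False)
    n_sig = int(assoc["significant"].sum())
    print(f"trait-ALFF association: {n_sig} of {len(assoc)} parcels "
          "significant after Bonferroni")

    sva_items = list(DEFAULT_SCALES["SVA"].items)
    behav = behavioral_rdm(items[sva_items], subject_ids=maps.subject_ids)
    res = isrsa_map(behav, maps)
    res.to_csv(TABLES / "isrsa.csv", index=False)
    top = res.sort_values("r", ascending=False).head(5)
    print("IS-RSA top parcels:")
    print(top[["parcel", "r", "p_raw", "p_bonferroni", "significant"]]
          .to_string(index=False))

    best = int(top["parcel"].iloc[0])
    r_obs, p_perm = mantel_permutation(behav, neural_rdm(maps, best),
                                       n_perm=5000, seed=SEED)
    pd.DataFrame([{"parcel": best, "r": round(r_obs, 4),
                   "p_mantel": p_perm}]).to_csv(
        TABLES / "mantel_followup.csv", index=False)
    print(f"Mantel follow-up on parcel {best}: r={r_obs:.3f}, p={p_perm:.4g}")


if __name__ == "__main__":
    main()
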