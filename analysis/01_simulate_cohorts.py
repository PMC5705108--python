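#!/usr/bin/env python
"""Simulate the study cohorts.

Generates the synthetic datasets every later analysis step reads:

* three "sites" (dsA, dsB, dsC) sampling subjects from the same two-subtype
  disease population over a shared baseline connectome -- the cross-dataset
  analogue of multi-site clinical cohorts;
* one homogeneous single-subtype cohort and one two-subtype cohort with
  replicate scans, for the split analyses.

Collections are written as TSV directories under scratch/cohorts/.
"""

from pathlib import Path

from fcrepro import experiments as ex
from fcrepro.io import write_scan_collection
from fcrepro.simulate import simulate_cohort

# simulated collections are bulky scratch data, not analysis results
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # three sites drawing from one heterogeneous population
    for k, name in enumerate(("dsA", "dsB", "dsC")):
        cfg = ex.cohort_config(
            "two_subtype", seed=SEED + k, dataset_id=name, base_seed=SEED
        )
        scans, truth = simulate_cohort(cfg)
        write_scan_collection(scans, OUT / name)
        truth.to_json(OUT / name / "ground_truth.json")
        print(f"{name}: {len(scans)} scans "
              f"({sum(s.group == 'NC' for s in scans)} NC)")

    # split-analysis cohorts
    for kind in ("homogeneous", "two_subtype"):
        cfg = ex.cohort_config(kind, seed=SEED + 10, dataset_id=f"split_{kind}")
        scans, truth = simulate_cohort(cfg)
        write_scan_collection(scans, OUT / f"split_{kind}")
        truth.to_json(OUT / f"split_{kind}" / "ground_truth.json")
        print(f"split_{kind}: {len(scans)} scans, "
              f"{len(truth.affected_pairs)} affected pairs")


if __name__ == "__main__":
    main()
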