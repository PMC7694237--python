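#!/usr/bin/env python
"""Simulate the default multi-institution cohort and write it to scratch/cohort.

24 institutions x 2 cases (A: right breast/ALND, S: left breast/SLNBx) x
2 arms (WBI, WBI+RNI), 6 institutions including IMN in the nodal target,
fractionation schemes drawn from the clinical pool, on a 96^3 grid at
2.5 mm. Downstream scripts read the written manifest.
"""

from collections import Counter
from pathlib import Path

from dummyrun import CohortConfig, generate_cohort, write_cohort

SEED = 1701
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    config = CohortConfig(seed=SEED)
    cohort = generate_cohort(config)
    manifest = write_cohort(cohort, OUT)

    schemes = Counter(
        f"{p.scheme.total_dose:g} Gy / {p.scheme.n_fractions} fx"
        for p in cohort.plans
        if p.case_id == "A" and p.arm == "WBI"
    )
    n_imn = sum(1 for i in cohort.institutions if i.includes_imn)
    print(f"cohort seed {SEED}: {len(cohort.plans)} plans "
          f"({config.n_institutions} institutions x 2 cases x 2 arms)")
    print(f"institutions including IMN in RNI: {n_imn}/{config.n_institutions}")
    print("fractionation schemes:")
    for scheme, count in schemes.most_common():
        print(f"  {scheme}: n={count}")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
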