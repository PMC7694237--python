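"""End-to-end study analysis: contour agreement, nodal doses, OAR dosimetry.

Given a cohort of plans (real or synthetic), the pipeline reproduces the
structure of a multi-institution dummy-run report:

* per case and arm — the 90% isodose contours of all institutions, their
  STAPLE reference contour, Fleiss's kappa, per-institution Dice vs the
  reference, and contour volume statistics;
* per case and nodal station — the relative nodal dose (RND) of each
  institution in each arm, with a paired Wilcoxon signed-rank comparison of
  the arms across institutions;
* per case — ipsilateral-lung V5/V10/V20/V30 and mean lung/heart dose on
  EQD2-converted grids (alpha/beta = 3 Gy), again arm-paired; and the heart
  mean dose contrast between IMN-including and IMN-excluding institutions
  within the WBI+RNI arm (an unpaired rank-sum test: the subgroups are
  disjoint institutions, so a signed-rank pairing does not exist).

The kappa/STAPLE analysis domain policy (dilated union of the rater
contours by default) is recorded in every report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementResult, cohort_agreement
from .cohort import ARMS, Cohort
from .core import (
    BinaryMask,
    NODAL_STATIONS,
    PlanRecord,
    StructureSet,
    convert_to_eqd2,
    extract_isodose_mask,
    mask_volume_cc,
)
from .dosimetry import mean_structure_dose, relative_nodal_dose, volume_receiving
from .staple import ConsensusResult, consensus_reference
from .stats import rank_sum_test, wilcoxon_signed_rank

__all__ = [
    "RunConfig",
    "CaseArmAgreement",
    "StudyReport",
    "analyze_case_arm",
    "build_study_report",
    "write_report",
]

log = logging.getLogger("dummyrun")

LUNG_THRESHOLDS = (5.0, 10.0, 20.0, 30.0)  # Gy (EQD2 space)


@dataclass
class RunConfig:
    """Analysis knobs; defaults follow the study conventions."""

    isodose_level: float = 0.9
    alpha_beta: float = 3.0  # Gy, for OAR EQD2 conversion
    domain_margin_voxels: int = 2  # kappa/STAPLE domain dilation
    domain_policy: str = "union_dilated"
    dvh_bin_width: float = 0.1  # Gy
    oar_on_eqd2: bool = True  # lung/heart metrics on EQD2 grids
    rnd_on_eqd2: bool = False  # RND on physical dose by default
    zero_policy: str = "drop"  # signed-rank zero handling
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaseArmAgreement:
    case_id: str
    arm: str
    isodose_masks: dict[str, BinaryMask]
    consensus: ConsensusResult
    kappa: AgreementResult
    dsc_table: pd.DataFrame  # institution_id, dsc (+ summary rows)
    volumes_cc: dict[str, float]


@dataclass
class StudyReport:
    agreement_table: pd.DataFrame
    nodal_table: pd.DataFrame
    nodal_long: pd.DataFrame
    oar_table: pd.DataFrame
    oar_long: pd.DataFrame
    imn_subgroup_table: pd.DataFrame
    dsc_long: pd.DataFrame
    config: RunConfig = field(default_factory=RunConfig)


def _plans_by(cohort: Cohort, case_id: str, arm: str) -> dict[str, PlanRecord]:
    out = {
        p.institution_id: p
        for p in cohort.plans
        if p.case_id == case_id and p.arm == arm
    }
    return dict(sorted(out.items()))


def analyze_case_arm(
    plans: dict[str, PlanRecord],
    structures: StructureSet,
    config: RunConfig | None = None,
) -> CaseArmAgreement:
    """Isodose contours, STAPLE reference, kappa and Dice for one case+arm cell."""
    config = config or RunConfig()
    if len(plans) < 2:
        raise ValueError("agreement analysis needs at least 2 institutions")
    case_ids = {p.case_id for p in plans.values()}
    arms = {p.arm for p in plans.values()}
    if len(case_ids) != 1 or len(arms) != 1:
        raise ValueError("plans must belong to a single case and arm")
    for p in plans.values():
        if p.dose.geometry != structures.geometry:
            raise ValueError(
                f"plan {p.institution_id} dose geometry incompatible with the structure set"
            )

    masks = {
        inst: extract_isodose_mask(p.dose, p.scheme, config.isodose_level)
        for inst, p in sorted(plans.items())
    }
    ordered = [masks[k] for k in sorted(masks)]
    consensus = consensus_reference(
        ordered,
        domain_policy=config.domain_policy,
        margin_voxels=config.domain_margin_voxels,
    )
    dsc_table, kappa = cohort_agreement(
        masks,
        consensus.consensus,
        domain=consensus.domain,
    )
    kappa.domain_policy = config.domain_policy
    volumes = {inst: mask_volume_cc(m) for inst, m in masks.items()}
    return CaseArmAgreement(
        case_id=case_ids.pop(),
        arm=arms.pop(),
        isodose_masks=masks,
        consensus=consensus,
        kappa=kappa,
        dsc_table=dsc_table,
        volumes_cc=volumes,
    )


def _median_range(values: np.ndarray) -> tuple[float, float, float]:
    return float(np.median(values)), float(values.min()), float(values.max())


def build_study_report(cohort: Cohort, config: RunConfig | None = None) -> StudyReport:
    """Run the full analysis for both cases and assemble the report tables."""
    config = config or RunConfig()
    case_ids = sorted(cohort.structures)

    # --- agreement (per case x arm) -----------------------------------
    agreement_rows = []
    dsc_long_rows = []
    for case_id in case_ids:
        for arm in ARMS:
            plans = _plans_by(cohort, case_id, arm)
            if len(plans) < 2:
                raise ValueError(f"case {case_id} arm {arm}: fewer than 2 plans")
            cell = analyze_case_arm(plans, cohort.structures[case_id], config)
            vols = np.array([cell.volumes_cc[k] for k in sorted(cell.volumes_cc)])
            dsc = cell.dsc_table[~cell.dsc_table["institution_id"].isin(["median", "min", "max"])]
            dsc_vals = dsc["dsc"].to_numpy()
            agreement_rows.append(
                {
                    "case_id": case_id,
                    "arm": arm,
                    "n_institutions": len(plans),
                    "volume_cc_median": float(np.median(vols)),
                    "volume_cc_min": float(vols.min()),
                    "volume_cc_max": float(vols.max()),
                    "kappa": cell.kappa.kappa,
                    "kappa_domain_policy": cell.kappa.domain_policy,
                    "dsc_median": float(np.median(dsc_vals)),
                    "dsc_min": float(dsc_vals.min()),
                    "dsc_max": float(dsc_vals.max()),
                }
            )
            for _, row in dsc.iterrows():
                dsc_long_rows.append(
                    {
                        "institution_id": row["institution_id"],
                        "case_id": case_id,
                        "arm": arm,
                        "dsc": row["dsc"],
                    }
                )
    agreement_table = pd.DataFrame(agreement_rows)
    dsc_long = pd.DataFrame(dsc_long_rows)

    # --- nodal doses (per case x station, arm-paired) ------------------
    nodal_long_rows = []
    for case_id in case_ids:
        structures = cohort.structures[case_id]
        for arm in ARMS:
            for inst, plan in _plans_by(cohort, case_id, arm).items():
                dose = plan.dose
                if config.rnd_on_eqd2:
                    dose = convert_to_eqd2(dose, plan.scheme, config.alpha_beta)
                for station in NODAL_STATIONS:
                    if station not in structures:
                        continue
                    rec = relative_nodal_dose(
                        dose,
                        structures[station],
                        plan.scheme,
                        institution_id=inst,
                        case_id=case_id,
                        arm=arm,
                        station=station,
                    )
                    nodal_long_rows.append(
                        {
                            "institution_id": inst,
                            "case_id": case_id,
                            "arm": arm,
                            "station": station,
                            "mean_dose": rec.mean_dose,
                            "rnd": rec.rnd,
                            "includes_imn": plan.includes_imn,
                        }
                    )
    nodal_long = pd.DataFrame(nodal_long_rows)

    nodal_rows = []
    for case_id in case_ids:
        for station in NODAL_STATIONS:
            sub = nodal_long[(nodal_long.case_id == case_id) & (nodal_long.station == station)]
            if sub.empty:
                continue
            wbi = sub[sub.arm == "WBI"].sort_values("institution_id")
            rni = sub[sub.arm == "WBI_RNI"].sort_values("institution_id")
            if list(wbi.institution_id) != list(rni.institution_id):
                raise ValueError(f"broken arm pairing for {case_id}/{station}")
            test = wilcoxon_signed_rank(
                wbi.rnd.to_numpy(), rni.rnd.to_numpy(), zero_policy=config.zero_policy
            )
            m_w, lo_w, hi_w = _median_range(wbi.rnd.to_numpy())
            m_r, lo_r, hi_r = _median_range(rni.rnd.to_numpy())
            nodal_rows.append(
                {
                    "case_id": case_id,
                    "station": station,
                    "n": len(wbi),
                    "rnd_median_wbi": m_w,
                    "rnd_min_wbi": lo_w,
                    "rnd_max_wbi": hi_w,
                    "rnd_median_wbi_rni": m_r,
                    "rnd_min_wbi_rni": lo_r,
                    "rnd_max_wbi_rni": hi_r,
                    "wilcoxon_w": test.statistic,
                    "p_value": test.p_value,
                    "test_method": test.method,
                }
            )
    nodal_table = pd.DataFrame(nodal_rows)

    # --- OAR dosimetry (per case, arm-paired) --------------------------
    oar_long_rows = []
    for case_id in case_ids:
        structures = cohort.structures[case_id]
        for arm in ARMS:
            for inst, plan in _plans_by(cohort, case_id, arm).items():
                dose = plan.dose
                if config.oar_on_eqd2:
                    dose = convert_to_eqd2(dose, plan.scheme, config.alpha_beta)
                row = {
                    "institution_id": inst,
                    "case_id": case_id,
                    "arm": arm,
                    "includes_imn": plan.includes_imn,
                }
                lung = structures["LUNG_IPSI"]
                for thr in LUNG_THRESHOLDS:
                    row[f"lung_v{thr:g}"] = volume_receiving(dose, lung, thr)
                row["lung_mean_dose"] = mean_structure_dose(dose, lung)
                row["heart_mean_dose"] = mean_structure_dose(dose, structures["HEART"])
                oar_long_rows.append(row)
    oar_long = pd.DataFrame(oar_long_rows)

    oar_metrics = [f"lung_v{t:g}" for t in LUNG_THRESHOLDS] + [
        "lung_mean_dose",
        "heart_mean_dose",
    ]
    oar_rows = []
    for case_id in case_ids:
        sub = oar_long[oar_long.case_id == case_id]
        wbi = sub[sub.arm == "WBI"].sort_values("institution_id")
        rni = sub[sub.arm == "WBI_RNI"].sort_values("institution_id")
        for metric in oar_metrics:
            test = wilcoxon_signed_rank(
                wbi[metric].to_numpy(), rni[metric].to_numpy(), zero_policy=config.zero_policy
            )
            m_w, lo_w, hi_w = _median_range(wbi[metric].to_numpy())
            m_r, lo_r, hi_r = _median_range(rni[metric].to_numpy())
            oar_rows.append(
                {
                    "case_id": case_id,
                    "metric": metric,
                    "n": len(wbi),
                    "median_wbi": m_w,
                    "min_wbi": lo_w,
                    "max_wbi": hi_w,
                    "median_wbi_rni": m_r,
                    "min_wbi_rni": lo_r,
                    "max_wbi_rni": hi_r,
                    "wilcoxon_w": test.statistic,
                    "p_value": test.p_value,
                    "test_method": test.method,
                }
            )
    oar_table = pd.DataFrame(oar_rows)

    # --- IMN subgroup: heart mean dose within WBI+RNI ------------------
    subgroup_rows = []
    for case_id in case_ids:
        sub = oar_long[(oar_long.case_id == case_id) & (oar_long.arm == "WBI_RNI")]
        with_imn = sub[sub.includes_imn]["heart_mean_dose"].to_numpy()
        without = sub[~sub.includes_imn]["heart_mean_dose"].to_numpy()
        if with_imn.size == 0 or without.size == 0:
            continue
        p = rank_sum_test(with_imn, without)
        subgroup_rows.append(
            {
                "case_id": case_id,
                "n_imn": int(with_imn.size),
                "n_no_imn": int(without.size),
                "heart_mean_median_imn": float(np.median(with_imn)),
                "heart_mean_median_no_imn": float(np.median(without)),
                "p_value": p,
                "test_method": "rank-sum (unpaired subgroups)",
            }
        )
    imn_subgroup_table = pd.DataFrame(subgroup_rows)

    return StudyReport(
        agreement_table=agreement_table,
        nodal_table=nodal_table,
        nodal_long=nodal_long,
        oar_table=oar_table,
        oar_long=oar_long,
        imn_subgroup_table=imn_subgroup_table,
        dsc_long=dsc_long,
        config=config,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report CSVs plus a JSON summary and run log; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "agreement.csv": report.agreement_table,
        "nodal_rnd.csv": report.nodal_table,
        "nodal_rnd_long.csv": report.nodal_long,
        "oar.csv": report.oar_table,
        "oar_long.csv": report.oar_long,
        "imn_subgroup.csv": report.imn_subgroup_table,
        "dsc_long.csv": report.dsc_long,
    }
    for name, tbl in tables.items():
        path = out / name
        tbl.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path

    summary = {
        "config": report.config.to_dict(),
        "agreement": report.agreement_table.to_dict(orient="records"),
        "nodal": report.nodal_table.to_dict(orient="records"),
        "oar": report.oar_table.to_dict(orient="records"),
        "imn_subgroup": report.imn_subgroup_table.to_dict(orient="records"),
        "notes": [
            "kappa/STAPLE domain: " + report.config.domain_policy,
            "OAR metrics on EQD2 grids" if report.config.oar_on_eqd2 else "OAR on physical dose",
            "RND on EQD2" if report.config.rnd_on_eqd2 else "RND on physical dose",
            "IMN subgroup contrast uses an unpaired rank-sum test",
        ],
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["report.json"] = out / "report.json"
    with open(out / "run.log", "w") as fh:
        fh.write("dummyrun analysis\n")
        fh.write(json.dumps(report.config.to_dict(), sort_keys=True) + "\n")
    paths["run.log"] = out / "run.log"
    return paths
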