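"""End-to-end orchestration: four SD maps per patient, the four-way
comparison, cohort aggregation and the threshold-sensitivity analysis.

Per patient the pipeline produces dSD_T, dSD_T+O, iSD_T and iSD_T+O,
then the two intra-method and two inter-method comparisons per scope.
The cohort stage summarises every (pair, scope, metric) as
median [p25, p75], tests volume contrasts with the rank-sum test,
correlates each metric with the input-mask volume (Spearman), and runs
the 5x3 (t_dSD, t_iSD) sensitivity grid with nRV per metric.
One failed patient is logged and skipped, never aborting the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort_stats, comparison_metrics as cm
from .cohort_stats import SensitivityGrid, sensitivity_analysis, summarize
from .core_geometry import (
    ROLE_T,
    ROLE_T_PLUS_O,
    SIDE_BILATERAL,
    LesionMask,
    Tractogram,
    VolumeMap,
    tractogram_cells,
)
from .direct_mapping import (
    DEFAULT_T_DSD,
    T_DSD_GRID,
    DirectSDResult,
    compute_direct_sd,
    density_map,
    population_average_density,
    symmetrize,
    threshold_dsd,
)
from .indirect_mapping import (
    DEFAULT_T_ISD,
    T_ISD_GRID,
    IndirectSDResult,
    compute_indirect_sd,
    threshold_isd,
)
from .phantom import Cohort, Patient

log = logging.getLogger(__name__)

METRICS = ("delta_vol_cm3", "dice", "corr")

#: the four comparisons of the framework: (label, (method, role), (method, role))
PAIRS = (
    ("iSD_T+O:iSD_T", ("indirect", ROLE_T_PLUS_O), ("indirect", ROLE_T)),
    ("dSD_T+O:dSD_T", ("direct", ROLE_T_PLUS_O), ("direct", ROLE_T)),
    ("iSD_T+O:dSD_T+O", ("indirect", ROLE_T_PLUS_O), ("direct", ROLE_T_PLUS_O)),
    ("iSD_T:dSD_T", ("indirect", ROLE_T), ("direct", ROLE_T)),
)


def pair_kind(label: str) -> str:
    """'intra' when both maps come from the same method, else 'inter'."""
    a, b = label.split(":")
    return "intra" if a[0] == b[0] else "inter"


@dataclass
class RunConfig:
    seed: int = 0
    n_patients: int = 20
    n_controls: int = 10
    displacement: bool = False
    t_dsd: float = DEFAULT_T_DSD
    t_isd: float = DEFAULT_T_ISD
    t_dsd_grid: tuple[float, ...] = T_DSD_GRID
    t_isd_grid: tuple[float, ...] = T_ISD_GRID
    compute_sensitivity: bool = True
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items()})
        for t in (cfg.t_dsd, *cfg.t_dsd_grid, cfg.t_isd, *cfg.t_isd_grid):
            if not 0.0 < float(t) < 1.0:
                raise ValueError(f"threshold {t} outside (0, 1)")
        return cfg


@dataclass
class PatientResult:
    pid: str
    side: str
    direct: dict[str, DirectSDResult]      # role -> result
    indirect: dict[str, IndirectSDResult]
    comparisons: list[dict]
    volumes: list[dict]


@dataclass
class CohortResult:
    avg_density: VolumeMap
    patient_results: list[PatientResult]
    comparisons: pd.DataFrame     # patient, side, pair, scope, metric columns
    volumes: pd.DataFrame         # patient, map, scope, volume_cm3
    summary: pd.DataFrame         # pair, scope, metric, median, p25, p75, n
    ranksum: pd.DataFrame         # pair, scope, statistic, p
    spearman: pd.DataFrame        # pair, metric, mask_role, rho, p, n
    sensitivity: SensitivityGrid | None


def _map_name(method: str, role: str) -> str:
    return f"{'iSD' if method == 'indirect' else 'dSD'}_{role}"


def build_avg_density(cohort: Cohort,
                      patient_cells: Sequence[tuple] | None = None) -> VolumeMap:
    """Symmetrised, lesion-excluded population average of whole-tractogram
    track-density maps (the dSD normaliser)."""
    densities, lesions = [], []
    for i, p in enumerate(cohort.patients):
        cells = patient_cells[i] if patient_cells is not None else None
        densities.append(density_map(p.tractogram, cells=cells))
        lesions.append(p.lesions[ROLE_T_PLUS_O])
    return symmetrize(population_average_density(densities, lesions))


def _scope_volumes(sig: VolumeMap, lesion: LesionMask, side: str) -> dict[str, float]:
    masked = cm.mask_sd_map(sig, lesion)
    out = {cm.SCOPE_WHOLE: cm.binary_volume_cm3(masked)}
    if side != SIDE_BILATERAL:
        ipsi, contra = cm.hemisphere_split(masked, side)
        out[cm.SCOPE_IPSI] = cm.binary_volume_cm3(ipsi)
        out[cm.SCOPE_CONTRA] = cm.binary_volume_cm3(contra)
    return out


def run_patient(patient: Patient, controls: Sequence[Tractogram],
                avg: VolumeMap, config: RunConfig,
                patient_cells=None, control_cells=None) -> PatientResult:
    """All four SD maps and the four comparisons for one patient."""
    cells = patient_cells if patient_cells is not None else \
        tractogram_cells(patient.tractogram)
    direct, indirect = {}, {}
    for role in (ROLE_T, ROLE_T_PLUS_O):
        lesion = patient.lesions[role]
        direct[role] = compute_direct_sd(patient.tractogram, lesion, avg,
                                         config.t_dsd, cells=cells)
        indirect[role] = compute_indirect_sd(lesion, controls,
                                             threshold=config.t_isd,
                                             atlas_cells=control_cells)
    results = {"direct": direct, "indirect": indirect}
    comparisons, volumes = [], []
    for label, (meth_a, role_a), (meth_b, role_b) in PAIRS:
        rows = cm.compare_pair(results[meth_a][role_a], results[meth_b][role_b],
                               patient.lesions[role_a], patient.lesions[role_b],
                               patient.side, pair_label=label)
        for r in rows:
            comparisons.append({
                "patient": patient.pid, "side": patient.side,
                "pair": r.pair_label, "scope": r.scope,
                "delta_vol_cm3": r.delta_vol_cm3,
                "dice": r.dice, "corr": r.corr})
    for method in ("indirect", "direct"):
        for role in (ROLE_T, ROLE_T_PLUS_O):
            sig = results[method][role].significant
            for scope, vol in _scope_volumes(sig, patient.lesions[role],
                                             patient.side).items():
                volumes.append({"patient": patient.pid,
                                "map": _map_name(method, role),
                                "scope": scope, "volume_cm3": vol})
    return PatientResult(pid=patient.pid, side=patient.side, direct=direct,
                         indirect=indirect, comparisons=comparisons,
                         volumes=volumes)


def _summary_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (pair, scope), sub in comparisons.groupby(["pair", "scope"]):
        for metric in METRICS:
            vals = sub[metric].tolist()
            try:
                s = summarize(vals, metric)
            except ValueError:
                continue
            rows.append({"pair": pair, "scope": scope, "metric": metric,
                         "median": s.median, "p25": s.p25, "p75": s.p75,
                         "n": s.n})
    return pd.DataFrame(rows)


def _ranksum_table(volumes: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum test of per-patient binary volumes, map A vs map B, per pair/scope."""
    rows = []
    piv = volumes.pivot_table(index="patient", columns=["map", "scope"],
                              values="volume_cm3")
    for label, (meth_a, role_a), (meth_b, role_b) in PAIRS:
        na, nb = _map_name(meth_a, role_a), _map_name(meth_b, role_b)
        for scope in (cm.SCOPE_WHOLE, cm.SCOPE_IPSI, cm.SCOPE_CONTRA):
            if (na, scope) not in piv.columns or (nb, scope) not in piv.columns:
                continue
            x = piv[(na, scope)].dropna()
            y = piv[(nb, scope)].dropna()
            if x.empty or y.empty:
                continue
            stat, p = cohort_stats.rank_sum_test(x.values, y.values)
            rows.append({"pair": label, "scope": scope, "statistic": stat,
                         "p": p, "n_a": len(x), "n_b": len(y)})
    return pd.DataFrame(rows)


def _spearman_table(comparisons: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Spearman of each whole-brain metric against the input-mask volume."""
    lesion_vol = {
        role: {p.pid: p.lesions[role].volume_cm3 for p in cohort.patients}
        for role in (ROLE_T, ROLE_T_PLUS_O)}
    rows = []
    whole = comparisons[comparisons["scope"] == cm.SCOPE_WHOLE]
    for pair, sub in whole.groupby("pair"):
        for metric in METRICS:
            for role in (ROLE_T, ROLE_T_PLUS_O):
                paired = [(v, lesion_vol[role][pid]) for pid, v in
                          zip(sub["patient"], sub[metric])
                          if v is not None and not pd.isna(v)]
                if len(paired) < 3:
                    continue
                mvals, lvals = zip(*paired)
                rho, p = cohort_stats.spearman_corr(lvals, mvals)
                rows.append({"pair": pair, "metric": metric, "mask_role": role,
                             "rho": rho, "p": p, "n": len(paired)})
    return pd.DataFrame(rows)


def _sensitivity(results: list[PatientResult], patients: dict[str, Patient],
                 avg: VolumeMap, config: RunConfig) -> SensitivityGrid:
    """Whole-brain metric medians over the full (t_iSD, t_dSD) grid."""
    rows = []
    for t_isd in config.t_isd_grid:
        for t_dsd in config.t_dsd_grid:
            per_cell: dict[str, dict[str, list]] = {
                label: {m: [] for m in METRICS} for label, _, _ in PAIRS}
            for res in results:
                patient = patients[res.pid]
                sig = {"direct": {}, "indirect": {}}
                cont = {"direct": {}, "indirect": {}}
                for role in (ROLE_T, ROLE_T_PLUS_O):
                    cont["direct"][role] = res.direct[role].dsd
                    sig["direct"][role] = threshold_dsd(res.direct[role].dsd,
                                                        avg, t_dsd)
                    cont["indirect"][role] = res.indirect[role].isd
                    sig["indirect"][role] = threshold_isd(res.indirect[role].isd,
                                                          t_isd)
                for label, (ma, ra), (mb, rb) in PAIRS:
                    row = cm.compare_pair(
                        cont[ma][ra], cont[mb][rb],
                        patients[res.pid].lesions[ra],
                        patients[res.pid].lesions[rb],
                        SIDE_BILATERAL,  # whole-brain scope only
                        pair_label=label,
                        sig_a=sig[ma][ra], sig_b=sig[mb][rb])[0]
                    per_cell[label]["delta_vol_cm3"].append(row.delta_vol_cm3)
                    per_cell[label]["dice"].append(row.dice)
                    per_cell[label]["corr"].append(row.corr)
            for label in per_cell:
                for metric, vals in per_cell[label].items():
                    try:
                        med = summarize(vals, metric).median
                    except ValueError:
                        med = None
                    rows.append({"pair": label, "metric": metric,
                                 "t_isd": t_isd, "t_dsd": t_dsd, "median": med})
    frame = pd.DataFrame(rows)
    return sensitivity_analysis(frame, config.t_dsd_grid, config.t_isd_grid)


def run_cohort(cohort: Cohort, config: RunConfig | None = None) -> CohortResult:
    """Run the full analysis on a cohort; deterministic given cohort + config."""
    config = config or RunConfig()
    patient_cells = [tractogram_cells(p.tractogram) for p in cohort.patients]
    control_cells = [tractogram_cells(c) for c in cohort.controls]
    avg = build_avg_density(cohort, patient_cells)
    results: list[PatientResult] = []
    for i, patient in enumerate(cohort.patients):
        try:
            results.append(run_patient(patient, cohort.controls, avg, config,
                                       patient_cells=patient_cells[i],
                                       control_cells=control_cells))
        except Exception:
            log.exception("patient %s failed; skipping", patient.pid)
    if not results:
        raise RuntimeError("every patient failed")
    comparisons = pd.DataFrame([r for res in results for r in res.comparisons])
    volumes = pd.DataFrame([v for res in results for v in res.volumes])
    summary = _summary_table(comparisons)
    ranksum = _ranksum_table(volumes)
    spearman = _spearman_table(comparisons, cohort)
    sens = None
    if config.compute_sensitivity:
        patients = {p.pid: p for p in cohort.patients}
        sens = _sensitivity(results, patients, avg, config)
    return CohortResult(avg_density=avg, patient_results=results,
                        comparisons=comparisons, volumes=volumes,
                        summary=summary, ranksum=ranksum, spearman=spearman,
                        sensitivity=sens)
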