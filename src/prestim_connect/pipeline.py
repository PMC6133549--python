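"""End-to-end analysis of a cohort of sessions.

Per infant: preprocess ROI series (high-pass filter at 0.01 Hz, demean),
extract pre-stimulus windows, build the connectivity matrix and network
means (full and brainstem-excluded), flag DVARS motion outliers, fit the
event-related GLM, and convert the canonical coefficient to percent BOLD
change over the activity mask. Cohort level: network/edge associations with
GA adjustment, the network-comparison RM-ANOVA, stimulus-number stability,
and the brainstem sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, InfantRecord
from .evoked import detect_motion_outliers, fit_glm, percent_bold_change
from .extraction import ROITimeSeriesSet, highpass_matrix, preprocess_series
from .hrf import BasisSet, build_design_matrix
from .psfc import (
    ConnectivityMatrix,
    build_connectivity_matrix,
    extract_prestim_windows,
    network_mean_psfc,
    psfc_by_stimulus,
)
from .stats import (
    BRAINSTEM_EXCLUSIONS,
    compare_network_connectivity,
    edgewise_association,
    psfc_association,
    sensitivity_excluding_brainstem,
    stimulus_stability,
)

__all__ = ["InfantResult", "CohortResults", "analyse_infant", "analyse_cohort", "report"]

HIGHPASS_HZ = 0.01


@dataclass(frozen=True)
class InfantResult:
    id: str
    ga_weeks: float
    connectivity: ConnectivityMatrix
    network_psfc: dict[str, float]
    per_stimulus_dpms: np.ndarray
    percent_change: float
    outlier_volumes: tuple[int, ...]
    dpms_edges: pd.Series


def _reduced_networks(networks: dict[str, tuple[str, ...]]) -> dict[str, tuple[str, ...]]:
    out = {}
    for net, dropped in BRAINSTEM_EXCLUSIONS.items():
        if net in networks:
            kept = tuple(r for r in networks[net] if r not in dropped)
            suffix = "noBrainstem" if net == "DPMS" else "no" + "".join(dropped)
            out[f"{net}_{suffix}"] = kept
    return out


def analyse_infant(
    record: InfantRecord,
    config: CohortConfig,
    basis: BasisSet,
    detect_outliers: bool = True,
) -> InfantResult:
    raw = ROITimeSeriesSet(tr=config.tr, series=record.roi_series)
    baselines = {k: float(v.mean()) for k, v in record.roi_series.items()}
    pre = preprocess_series(raw, highpass_hz=HIGHPASS_HZ)

    windows = extract_prestim_windows(pre, record.protocol)
    cm = build_connectivity_matrix(windows, networks=config.networks)
    network_psfc = {
        net: network_mean_psfc(cm, members)
        for net, members in config.networks.items()
    }
    for name, members in _reduced_networks(config.networks).items():
        network_psfc[name] = network_mean_psfc(cm, members)
    per_stim = psfc_by_stimulus(cm, config.networks["DPMS"])

    outliers = (
        detect_motion_outliers(pre.to_matrix()) if detect_outliers else ()
    )
    design = build_design_matrix(
        record.protocol, basis, config.n_volumes, config.tr, outliers=outliers
    )
    regressor_peak = float(design.task[:, 0].max())
    # filter the task regressors with the same high-pass operator as the data
    H = highpass_matrix(config.n_volumes, config.tr, HIGHPASS_HZ)
    filtered = design.matrix.copy()
    filtered[:, : design.n_task_regressors] = H @ design.task
    design_f = type(design)(
        matrix=filtered,
        labels=design.labels,
        n_task_regressors=design.n_task_regressors,
        tr=design.tr,
    )
    fits = {roi: fit_glm(pre.series[roi], design_f) for roi in config.active_rois}
    pc = percent_bold_change(fits, baselines, regressor_peak=regressor_peak)

    dpms = config.networks["DPMS"]
    edges = {}
    for i, a in enumerate(dpms):
        for b in dpms[i + 1 :]:
            ia, ib = cm.labels.index(a), cm.labels.index(b)
            edges[f"{a}-{b}"] = cm.matrix[ia, ib]

    return InfantResult(
        id=record.id,
        ga_weeks=record.ga_weeks,
        connectivity=cm,
        network_psfc=network_psfc,
        per_stimulus_dpms=per_stim,
        percent_change=pc.value,
        outlier_volumes=outliers,
        dpms_edges=pd.Series(edges),
    )


@dataclass(frozen=True)
class CohortResults:
    config: CohortConfig
    infants: pd.DataFrame  # one row per infant: psFC means, percent change, GA
    edge_table: pd.DataFrame  # infants x DPMS edges
    per_stimulus: pd.DataFrame  # infants x stimulus number
    connectivity: tuple[ConnectivityMatrix, ...]

    @property
    def network_columns(self) -> list[str]:
        return [c for c in self.infants.columns if c.startswith("psfc_")]


def analyse_cohort(cohort: Cohort, detect_outliers: bool = True) -> CohortResults:
    rows, edge_rows, stim_rows, cms = [], [], [], []
    for rec in cohort.infants:
        res = analyse_infant(
            rec, cohort.config, cohort.basis, detect_outliers=detect_outliers
        )
        row = {
            "id": res.id,
            "ga_weeks": res.ga_weeks,
            "percent_change": res.percent_change,
            "latent_coupling": rec.latent_coupling,
            "true_amplitude_pct": rec.true_amplitude_pct,
            "n_outliers": len(res.outlier_volumes),
        }
        row.update({f"psfc_{k}": v for k, v in res.network_psfc.items()})
        rows.append(row)
        edge_rows.append(res.dpms_edges)
        stim_rows.append(res.per_stimulus_dpms)
        cms.append(res.connectivity)
    infants = pd.DataFrame(rows).set_index("id")
    edge_table = pd.DataFrame(edge_rows, index=infants.index)
    per_stimulus = pd.DataFrame(
        np.vstack(stim_rows),
        index=infants.index,
        columns=[f"stim{j + 1}" for j in range(len(stim_rows[0]))],
    )
    return CohortResults(
        config=cohort.config,
        infants=infants,
        edge_table=edge_table,
        per_stimulus=per_stimulus,
        connectivity=tuple(cms),
    )


def report(results: CohortResults) -> dict:
    """Full results structure: associations, ANOVAs, sensitivity."""
    inf = results.infants
    y = inf["percent_change"].to_numpy()
    ga = inf["ga_weeks"].to_numpy()

    associations = {
        net: psfc_association(
            y, inf[f"psfc_{net}"].to_numpy(), ga, label=net
        ).to_dict()
        for net in results.config.networks
    }
    edges = edgewise_association(results.edge_table, y, ga)
    net_cols = [f"psfc_{n}" for n in results.config.networks]
    network_table = inf[net_cols].rename(
        columns=lambda c: c.removeprefix("psfc_")
    )
    network_anova = compare_network_connectivity(network_table)
    stability = stimulus_stability(results.per_stimulus)
    excluded_cols = [
        c
        for c in inf.columns
        if c.startswith("psfc_") and ("_no" in c)
    ]
    sensitivity = {
        k: v.to_dict()
        for k, v in sensitivity_excluding_brainstem(
            inf[excluded_cols].rename(columns=lambda c: c.removeprefix("psfc_")),
            y,
            ga,
        ).items()
    }
    return {
        "n_infants": int(len(inf)),
        "network_mean_psfc": {
            net: float(inf[f"psfc_{net}"].mean()) for net in results.config.networks
        },
        "associations": associations,
        "edgewise": edges.to_dict(orient="records"),
        "network_anova": network_anova.to_dict(),
        "stimulus_stability": stability.to_dict(),
        "sensitivity": sensitivity,
    }
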