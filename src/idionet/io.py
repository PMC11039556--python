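"""Readers and writers for the pipeline's exchange formats.

Canonical formats: long-format EMA CSV (one row per participant x beep, with
an explicit missing flag), IDS-SR CSV (participant_id, item_1..item_30),
per-person network JSON and edge-list CSVs, and a ground-truth JSON sidecar
for simulated studies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gvar import GVARModel
from .invariance import INITResult
from .preprocess import score_ids_sr
from .series import StudyDesign, SymptomSeries
from .simulate import SimulatedStudy, TrueGVAR


# ---------------------------------------------------------------------------
# EMA long format
# ---------------------------------------------------------------------------


def write_ema_long(series_map: dict[str, SymptomSeries], path) -> None:
    """Write series as long-format CSV: participant_id, day, beep, values,
    missing flag. Missing beeps keep their grid row with empty value cells."""
    rows = []
    for pid, s in series_map.items():
        day, beep, _ = s.design.grid()
        obs = s.observed_mask
        for i in range(s.n_beeps):
            row = {"participant_id": pid, "day": int(day[i]), "beep": int(beep[i])}
            for j, col in enumerate(s.columns):
                row[col] = s.values[i, j] if obs[i, j] else np.nan
            row["missing"] = int(not obs[i].any())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_ema_long(
    path,
    design: StudyDesign | None = None,
    columns: tuple[str, ...] | None = None,
    value_range: tuple[float, float] | None = None,
) -> dict[str, SymptomSeries]:
    """Read long-format EMA CSV into per-participant series.

    The beep grid is reconstructed from (day, beep) and validated against the
    design; duplicate (participant, day, beep) rows are a hard error naming
    the offending line. ``value_range=(0, 100)`` enables VAS range checking
    for raw data (simulated latent-scale series are unbounded).
    """
    design = design or StudyDesign()
    df = pd.read_csv(path)
    required = {"participant_id", "day", "beep"}
    if not required.issubset(df.columns):
        raise ValueError(f"EMA CSV must have columns {sorted(required)}")
    value_cols = [
        c for c in df.columns if c not in required and c != "missing"
    ]
    if columns is not None:
        unknown = [c for c in value_cols if c not in columns]
        if unknown:
            raise ValueError(f"unknown value columns: {unknown}")
        value_cols = list(columns)
    dup = df.duplicated(subset=["participant_id", "day", "beep"])
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        rec = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate beep at line {line}: participant {rec['participant_id']}"
            f", day {rec['day']}, beep {rec['beep']}"
        )
    bad_day = ~df["day"].between(1, design.n_days)
    bad_beep = ~df["beep"].between(1, design.beeps_per_day)
    if bad_day.any() or bad_beep.any():
        line = int((bad_day | bad_beep).idxmax()) + 2
        raise ValueError(f"day/beep outside the design grid at line {line}")
    if value_range is not None:
        lo, hi = value_range
        vals = df[value_cols].to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < lo) | (vals > hi))
        if bad.any():
            line = int(np.argwhere(bad.any(axis=1))[0][0]) + 2
            raise ValueError(f"value outside [{lo}, {hi}] at line {line}")
    out: dict[str, SymptomSeries] = {}
    T = design.max_assessments
    for pid, sub in df.groupby("participant_id", sort=False):
        values = np.full((T, len(value_cols)), np.nan)
        t_idx = (sub["day"].to_numpy() - 1) * design.beeps_per_day + (
            sub["beep"].to_numpy() - 1
        )
        values[t_idx] = sub[value_cols].to_numpy(dtype=float)
        out[str(pid)] = SymptomSeries(
            participant_id=str(pid),
            values=values,
            columns=tuple(value_cols),
            design=design,
        )
    return out


def read_ids_sr(path) -> list:
    """Read an IDS-SR CSV (participant_id, item_1..item_30) and score it."""
    df = pd.read_csv(path)
    item_cols = [f"item_{i}" for i in range(1, 31)]
    missing = [c for c in item_cols if c not in df.columns]
    if missing:
        raise ValueError(f"IDS-SR CSV lacks columns: {missing}")
    results = []
    for _, row in df.iterrows():
        items = [None if pd.isna(row[c]) else float(row[c]) for c in item_cols]
        results.append(score_ids_sr(items, participant_id=str(row["participant_id"])))
    return results


# ---------------------------------------------------------------------------
# Simulated-study ground truth
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, ema_path, truth_path) -> None:
    """Write a simulated study: EMA CSV plus a ground-truth JSON sidecar."""
    write_ema_long(study.series, ema_path)
    sidecar = {
        "seed": study.seed,
        "design": {
            "n_days": study.design.n_days,
            "beeps_per_day": study.design.beeps_per_day,
        },
        "participants": {
            pid: {
                "mu": t.mu.tolist(),
                "B": t.B.tolist(),
                "K": t.K.tolist(),
                "severity": study.severity[pid],
            }
            for pid, t in study.truths.items()
        },
        "groups": {str(k): v for k, v in study.groups.items()},
    }
    Path(truth_path).write_text(json.dumps(sidecar, indent=1))


def read_truth(truth_path) -> dict[str, TrueGVAR]:
    data = json.loads(Path(truth_path).read_text())
    return {
        pid: TrueGVAR(
            mu=np.array(rec["mu"]), B=np.array(rec["B"]), K=np.array(rec["K"])
        )
        for pid, rec in data["participants"].items()
    }


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------


def model_to_dict(model: GVARModel) -> dict:
    return {
        "mu": model.mu.tolist(),
        "B": model.B.tolist(),
        "K": model.K.tolist(),
        "Omega": model.Omega.tolist(),
        "loglik": model.loglik,
        "n_params": model.n_params,
        "columns": list(model.columns),
        "convergence": None
        if model.convergence is None
        else {
            "converged": model.convergence.converged,
            "n_iter": model.convergence.n_iter,
            "final_delta": model.convergence.final_delta,
        },
    }


def write_model_json(model: GVARModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def write_edge_lists(model: GVARModel, temporal_path, contemporaneous_path) -> None:
    """Edge-list CSVs: temporal (from, to, weight) and contemporaneous
    (i, j, weight, upper triangle only)."""
    names = model.columns or tuple(f"v{i+1}" for i in range(model.p))
    temp = [
        {"from": names[j], "to": names[i], "weight": model.B[i, j]}
        for i in range(model.p)
        for j in range(model.p)
        if model.B[i, j] != 0.0
    ]
    cont = [
        {"i": names[i], "j": names[j], "weight": model.Omega[i, j]}
        for i in range(model.p)
        for j in range(i + 1, model.p)
        if model.Omega[i, j] != 0.0
    ]
    pd.DataFrame(temp, columns=["from", "to", "weight"]).to_csv(
        temporal_path, index=False
    )
    pd.DataFrame(cont, columns=["i", "j", "weight"]).to_csv(
        contemporaneous_path, index=False
    )


def write_graphml(model: GVARModel, path, which: str = "temporal") -> None:
    """Optional GraphML export for standard graph tooling."""
    import networkx as nx

    names = model.columns or tuple(f"v{i+1}" for i in range(model.p))
    if which == "temporal":
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for i in range(model.p):
            for j in range(model.p):
                if model.B[i, j] != 0.0:
                    g.add_edge(names[j], names[i], weight=float(model.B[i, j]))
    elif which == "contemporaneous":
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(model.p):
            for j in range(i + 1, model.p):
                if model.Omega[i, j] != 0.0:
                    g.add_edge(names[i], names[j], weight=float(model.Omega[i, j]))
    else:
        raise ValueError("which must be 'temporal' or 'contemporaneous'")
    nx.write_graphml(g, path)


def init_report_frame(results: list[INITResult]) -> pd.DataFrame:
    """One row per severity group: logliks, parameter counts, AICs, flag."""
    return pd.DataFrame(
        [
            {
                "severity": r.group_id,
                "size": r.size,
                "loglik_free": r.loglik_free,
                "loglik_hom": r.loglik_constrained,
                "n_params_free": r.n_params_free,
                "n_params_hom": r.n_params_constrained,
                "aic_het": r.aic_het,
                "aic_hom": r.aic_hom,
                "heterogeneous": r.heterogeneous,
            }
            for r in results
        ]
    )
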