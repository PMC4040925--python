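"""Pipeline orchestration: manifest-driven end-to-end analysis.

Reads a manifest of measurement files (FCCS trace pairs, FCS traces, FRAP
curves), runs correlate -> summarize -> QC -> Ka/score, then cohort
statistics, network inference and co-dynamics, and writes a tidy results
table plus network and report artifacts.  Every excluded measurement is
logged with the criterion that triggered it.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationSet, calibration_chain
from .correlation import IntensityTrace, average_curves, multitau_correlate, summarize_curve
from .fccs import QcThresholds, analyze_summaries
from .kinetics import dynamics_profile, fit_fcs, fit_frap, normalize_frap
from .stats_network import (
    EdgeRecord,
    NearFarDataset,
    build_network,
    co_dynamics_distance,
    find_ternary_complexes,
    infer_mutual_exclusivity,
    median_association_test,
    near_far_coupled_test,
    near_far_uncoupled_test,
)

__all__ = ["PipelineConfig", "Manifest", "ParseError", "read_trace_csv", "read_frap_csv", "run_pipeline"]

MANIFEST_COLUMNS = ["id", "type", "path", "label", "cell_line", "location", "treatment"]
MEASUREMENT_TYPES = ("fccs", "fcs", "frap")
LOCATIONS = ("cytosol", "near", "far")


class ParseError(ValueError):
    """A malformed input file (message names file, line and column)."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; round-trips through JSON."""

    manifest: str = "manifest.csv"
    output_dir: str = "results"
    calibration: dict = field(default_factory=dict)  # CalibrationSet overrides
    recompute_calibration: bool = False  # run the dye calibration chain instead
    qc: dict = field(default_factory=dict)  # QcThresholds overrides
    bins_per_stage: int = 16
    negative_pair: str = "negative"  # label of the negative-control cohort
    primary_cell_line: str = ""  # default: first cell line alphabetically
    p_primary: float = 1e-4
    p_secondary: float = 0.02
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        # output_dir is excluded: it does not affect any computed value
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def calibration_set(self) -> CalibrationSet:
        if self.recompute_calibration:
            return calibration_chain()
        return CalibrationSet(**self.calibration)

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(**self.qc)


@dataclass
class Manifest:
    """Validated table of measurement inputs."""

    rows: pd.DataFrame
    root: Path

    @classmethod
    def read(cls, path) -> "Manifest":
        path = Path(path)
        rows = pd.read_csv(path, dtype=str).fillna("")
        missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
        if missing:
            raise ParseError(f"{path}: manifest is missing columns {missing}")
        if rows["id"].duplicated().any():
            dupes = sorted(rows.loc[rows["id"].duplicated(), "id"])
            raise ParseError(f"{path}: duplicate measurement ids {dupes}")
        bad_type = rows.loc[~rows["type"].isin(MEASUREMENT_TYPES), "type"]
        if len(bad_type):
            raise ParseError(f"{path}: unknown measurement types {sorted(set(bad_type))}")
        bad_loc = rows.loc[~rows["location"].isin(LOCATIONS), "location"]
        if len(bad_loc):
            raise ParseError(f"{path}: unknown locations {sorted(set(bad_loc))}")
        return cls(rows=rows, root=path.parent)

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.root / p


def _float_field(value: str, path, line_no: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"{path}:{line_no}: cannot parse {column}={value!r} as a number "
            "(dot-decimal notation required)"
        ) from None


def read_trace_csv(path, bin_width: float | None = None, dark_rate: float = 0.0):
    """Read a (time_s, counts_green, counts_red[, trace]) CSV.

    Returns a list of (green, red) :class:`IntensityTrace` pairs, one per
    distinct value of the optional ``trace`` column.  The bin width is taken
    from the time column unless given explicitly.
    """
    groups: dict[str, list[tuple[float, float, float]]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"time_s", "counts_green", "counts_red"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            have = reader.fieldnames or []
            missing = sorted(required.difference(have))
            raise ParseError(f"{path}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            if any(row.get(k) is None for k in required):
                raise ParseError(f"{path}:{line_no}: wrong number of fields")
            t = _float_field(row["time_s"], path, line_no, "time_s")
            cg = _float_field(row["counts_green"], path, line_no, "counts_green")
            cr = _float_field(row["counts_red"], path, line_no, "counts_red")
            groups.setdefault(row.get("trace") or "0", []).append((t, cg, cr))
    pairs = []
    for key in sorted(groups):
        arr = np.array(groups[key])
        if arr.shape[0] < 2:
            raise ParseError(f"{path}: trace {key!r} has fewer than 2 bins")
        dt = bin_width if bin_width is not None else float(arr[1, 0] - arr[0, 0])
        if dt <= 0:
            raise ParseError(f"{path}: non-increasing time column")
        pairs.append(
            (
                IntensityTrace(dt, arr[:, 1], "G", dark_rate=dark_rate),
                IntensityTrace(dt, arr[:, 2], "R", dark_rate=dark_rate),
            )
        )
    return pairs


def read_frap_csv(path):
    """Read a (time_s, intensity, background) CSV plus its JSON sidecar.

    Returns (time, intensity, background, bleach_index); the sidecar
    ``<path>.json`` supplies ``bleach_index`` (default 10).
    """
    rows = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"time_s", "intensity", "background"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            have = reader.fieldnames or []
            missing = sorted(required.difference(have))
            raise ParseError(f"{path}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            if any(row.get(k) is None for k in required):
                raise ParseError(f"{path}:{line_no}: wrong number of fields")
            rows.append(
                tuple(_float_field(row[k], path, line_no, k) for k in ("time_s", "intensity", "background"))
            )
    arr = np.array(rows)
    bleach_index = 10
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        with open(sidecar, "r", encoding="utf-8") as fh:
            bleach_index = int(json.load(fh).get("bleach_index", 10))
    return arr[:, 0], arr[:, 1], arr[:, 2], bleach_index


def _analyze_fccs_file(path, config: PipelineConfig, calib: CalibrationSet, meta: dict):
    pairs = read_trace_csv(path, dark_rate=calib.dark_rate)
    curves = {"GG": [], "RR": [], "RG": []}
    rate_g = np.mean([g.count_rate for g, _ in pairs])
    rate_r = np.mean([r.count_rate for _, r in pairs])
    for green, red in pairs:
        curves["GG"].append(multitau_correlate(green, bins_per_stage=config.bins_per_stage))
        curves["RR"].append(multitau_correlate(red, bins_per_stage=config.bins_per_stage))
        curves["RG"].append(multitau_correlate(red, green, bins_per_stage=config.bins_per_stage))
    summaries = {k: summarize_curve(average_curves(v)) for k, v in curves.items()}
    return analyze_summaries(
        summaries["GG"],
        summaries["RR"],
        summaries["RG"],
        float(rate_g),
        float(rate_r),
        calib,
        config.qc_thresholds(),
        **meta,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline described by ``config`` and write all artifacts.

    Returns the report dictionary.  Unreadable input files are recorded in
    the exclusion log and do not abort the run.
    """
    manifest = Manifest.read(config.manifest)
    calib = config.calibration_set()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results_rows: list[dict] = []
    exclusions: list[dict] = []
    frap_by_protein: dict[str, list[dict]] = {}
    fcs_by_protein: dict[str, list[dict]] = {}

    for row in manifest.rows.sort_values("id").itertuples(index=False):
        path = manifest.resolve(row.path)
        meta = {
            "pair": row.label,
            "cell_id": row.id,
            "cell_line": row.cell_line,
            "location": row.location or "cytosol",
            "treatment": row.treatment or "none",
        }
        try:
            if row.type == "fccs":
                m = _analyze_fccs_file(path, config, calib, meta)
                results_rows.append(
                    {
                        "id": row.id,
                        "type": "fccs",
                        "pair": row.label,
                        "cell_line": row.cell_line,
                        "location": meta["location"],
                        "treatment": meta["treatment"],
                        "n_gg": m.n_gg,
                        "n_rr": m.n_rr,
                        "n_rg": m.n_rg,
                        "g0_gg": m.summary_gg.g0,
                        "g0_rr": m.summary_rr.g0,
                        "g0_rg": m.summary_rg.g0,
                        "count_rate_g": m.count_rate_g,
                        "count_rate_r": m.count_rate_r,
                        "ka_fl": m.ka.ka_fl if m.ka else math.nan,
                        "score": m.score,
                        "qc_passed": m.qc.passed,
                        "qc_flags": ";".join(m.qc.flags),
                    }
                )
                if not m.qc.passed:
                    exclusions.append(
                        {"id": row.id, "type": "fccs", "reason": ";".join(m.qc.flags)}
                    )
            elif row.type == "fcs":
                pairs = read_trace_csv(path, dark_rate=calib.dark_rate)
                curve = average_curves(
                    [multitau_correlate(g, bins_per_stage=config.bins_per_stage) for g, _ in pairs]
                )
                fit = fit_fcs(curve, fix_s=calib.s)
                results_rows.append(
                    {
                        "id": row.id,
                        "type": "fcs",
                        "pair": row.label,
                        "cell_line": row.cell_line,
                        "location": meta["location"],
                        "treatment": meta["treatment"],
                        "tau_d": fit.tau_d,
                        "n_fit": fit.n,
                        "r_squared": fit.r_squared,
                        "qc_passed": fit.converged,
                        "qc_flags": "" if fit.converged else "fit_failed",
                    }
                )
                if fit.converged:
                    fcs_by_protein.setdefault(row.label, []).append({"tau_d": fit.tau_d})
                else:
                    exclusions.append({"id": row.id, "type": "fcs", "reason": "fit_failed"})
            elif row.type == "frap":
                t, intensity, background, bleach = read_frap_csv(path)
                t_post, norm = normalize_frap(t, intensity, background, n_prebleach=bleach)
                fit = fit_frap(t_post, norm)
                results_rows.append(
                    {
                        "id": row.id,
                        "type": "frap",
                        "pair": row.label,
                        "cell_line": row.cell_line,
                        "location": meta["location"],
                        "treatment": meta["treatment"],
                        "mobile_fraction": fit.mobile_fraction,
                        "tau_half": fit.tau_half,
                        "r_squared": fit.r_squared,
                        "qc_passed": fit.valid,
                        "qc_flags": "" if fit.valid else "r_squared_fail",
                    }
                )
                if fit.valid:
                    frap_by_protein.setdefault(row.label, []).append(
                        {"tau_half": fit.tau_half, "mobile_fraction": fit.mobile_fraction}
                    )
                else:
                    exclusions.append({"id": row.id, "type": "frap", "reason": "r_squared_fail"})
        except (OSError, ParseError, ValueError) as exc:
            exclusions.append({"id": row.id, "type": row.type, "reason": f"error: {exc}"})

    results = pd.DataFrame(results_rows)
    header = (
        f"# fccskit {__version__} config_hash={config.config_hash()} seed={config.seed}\n"
    )
    results_path = outdir / "results.csv"
    with open(results_path, "w", encoding="utf-8") as fh:
        fh.write(header)
        results.to_csv(fh, index=False)
    pd.DataFrame(exclusions, columns=["id", "type", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False
    )

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_measurements": len(results_rows),
        "n_excluded": len(exclusions),
    }

    # ---- cohort statistics & network ------------------------------------
    pair_stats, edge_records = _cohort_statistics(results, config)
    report["pair_stats"] = pair_stats
    if edge_records:
        net = build_network(edge_records, config.p_primary, config.p_secondary)
        cliques = find_ternary_complexes(net)
        exclusivity = infer_mutual_exclusivity(net)
        report["network_edges"] = [list(e) for e in net.edges]
        report["ternary_complexes"] = [list(c) for c in cliques]
        report["mutual_exclusivity"] = [[hub, list(p)] for hub, p in exclusivity]
        _write_network(outdir, net)

    # ---- dynamics profile -----------------------------------------------
    merged: dict[str, list[dict]] = {}
    for protein, fits in frap_by_protein.items():
        merged[protein] = list(fits)
    if merged:
        profile = dynamics_profile(merged, min_fits=3)
        for protein, fits in fcs_by_protein.items():
            if protein in profile.medians:
                taus = np.array([f["tau_d"] for f in fits])
                profile.medians[protein]["tau_d"] = float(np.median(taus))
        report["dynamics_profile"] = profile.medians
        try:
            proteins, dist = co_dynamics_distance(profile)
            report["co_dynamics"] = {
                "proteins": proteins,
                "distance_matrix": dist.round(6).tolist(),
            }
        except ValueError:
            pass

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, ensure_ascii=False, default=str)
    return report


def _cohort_statistics(results: pd.DataFrame, config: PipelineConfig):
    """Association tests vs the negative control and near/far comparisons."""
    pair_stats: dict = {}
    edge_records: list[EdgeRecord] = []
    if results.empty or "score" not in results.columns:
        return pair_stats, edge_records
    fccs = results[(results["type"] == "fccs") & results["qc_passed"]].copy()
    fccs = fccs[np.isfinite(fccs["score"])]
    if fccs.empty:
        return pair_stats, edge_records

    cell_lines = sorted(fccs["cell_line"].unique())
    primary = config.primary_cell_line or cell_lines[0]

    for pair in sorted(fccs["pair"].unique()):
        if pair == config.negative_pair:
            continue
        stats_entry: dict = {}
        p_by_line: dict[str, float] = {}
        for line in cell_lines:
            sub = fccs[fccs["cell_line"] == line]
            pair_scores = sub.loc[sub["pair"] == pair, "score"].to_numpy()
            neg_scores = sub.loc[sub["pair"] == config.negative_pair, "score"].to_numpy()
            if pair_scores.size == 0 or neg_scores.size == 0:
                continue
            res = median_association_test(pair_scores, neg_scores)
            p_by_line[line] = res.p_value
        stats_entry["p_by_cell_line"] = p_by_line

        near = fccs[(fccs["pair"] == pair) & (fccs["location"] == "near")]["score"].to_numpy()
        far = fccs[(fccs["pair"] == pair) & (fccs["location"] == "far")]["score"].to_numpy()
        if near.size and far.size:
            if near.size == far.size:
                stats_entry["near_far_coupled"] = near_far_coupled_test(
                    NearFarDataset(pair, near, far)
                )
            stats_entry["near_far_uncoupled"] = near_far_uncoupled_test(near, far)
        pair_stats[pair] = stats_entry

        if primary in p_by_line and ":" in pair:
            a, b = pair.split(":", 1)
            secondary_p = None
            for line, p in p_by_line.items():
                if line != primary:
                    secondary_p = p
                    break
            ka = fccs.loc[fccs["pair"] == pair, "ka_fl"].to_numpy()
            ka = ka[np.isfinite(ka)]
            ka_median = float(np.median(ka)) if ka.size else math.nan
            ka_mad = float(np.median(np.abs(ka - ka_median))) if ka.size else math.nan
            score_median = float(np.median(fccs.loc[fccs["pair"] == pair, "score"]))
            edge_records.append(
                EdgeRecord(a, b, p_by_line[primary], secondary_p, ka_median, ka_mad, score_median)
            )
    return pair_stats, edge_records


def _write_network(outdir: Path, net) -> None:
    with open(outdir / "network.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tp_primary\tp_secondary\tka_median\tka_mad\n")
        for a, b in net.edges:
            data = net.graph.edges[a, b]
            fh.write(
                f"{a}\t{b}\t{data.get('p_primary', '')}\t{data.get('p_secondary', '')}\t"
                f"{data.get('ka_median', '')}\t{data.get('ka_mad', '')}\n"
            )
    sanitized = nx.Graph()
    sanitized.add_nodes_from(net.graph.nodes)
    for a, b, data in net.graph.edges(data=True):
        sanitized.add_edge(a, b, **{k: v for k, v in data.items() if v is not None})
    nx.write_graphml(sanitized, outdir / "network.graphml")
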