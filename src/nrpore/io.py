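"""File formats, run configuration and report generation.

Reflectivity curves travel as 3- or 4-column delimited text (Q, R, dR[,
dQ]) with ``# key: value`` comment headers carrying the contrast metadata;
ORSO-style ``.ort`` headers (``# key: value`` YAML-ish lines) are accepted
by the same parser.  Kinetic traces are 3-4 column text (t, y, dy[,
t_window]).  Run configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .inference import ContrastDataset, FitResult
from .kinetics import KineticTrace
from .materials import SolventContrast

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "read_trace",
    "write_trace",
    "load_config",
    "run_pipeline",
    "format_fit_report",
]

log = logging.getLogger("nrpore")

DEFAULT_DQ_OVER_Q = 0.04

_CONTRAST_PRESETS = {"d2o": 1.0, "si-mw": 0.38, "simw": 0.38, "h2o": 0.0}


class ReflectivityParseError(ValueError):
    pass


def _parse_header_line(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    for sep in (":", "="):
        if sep in body:
            key, _, value = body.partition(sep)
            key = key.strip().lower().replace(" ", "_")
            value = value.strip()
            if key and value and key not in meta:
                meta[key] = value
            return


def read_reflectivity(path: str | Path) -> ContrastDataset:
    """Parse a reflectivity file into a :class:`ContrastDataset`.

    Accepts whitespace- or comma-delimited columns Q, R, dR and optionally
    dQ (FWHM); when the dQ column is absent it is filled from the nominal
    4% dQ/Q instrument resolution.  Contrast metadata is read from header
    comments (``name``, ``x_d2o``, ``protein_isotope``); unknown headers are
    kept in ``metadata``.  Malformed rows raise errors naming the line.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_header_line(line, meta)
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ReflectivityParseError(
                    f"{path.name}:{lineno}: non-numeric value in {line!r}"
                ) from None
            if len(values) < 3:
                raise ReflectivityParseError(
                    f"{path.name}:{lineno}: expected >=3 columns (Q R dR), got {len(values)}"
                )
            rows.append(values[:4])
    if not rows:
        raise ReflectivityParseError(f"{path.name}: no data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows])
    q, r, dr = data[:, 0], data[:, 1], data[:, 2]
    if np.any(np.diff(q) <= 0):
        i = int(np.argmax(np.diff(q) <= 0)) + 2
        raise ReflectivityParseError(f"{path.name}: Q not strictly increasing near data row {i}")
    if np.any(dr <= 0):
        i = int(np.argmax(dr <= 0)) + 1
        raise ReflectivityParseError(f"{path.name}: non-positive dR at data row {i}")
    dq = data[:, 3] if ncol >= 4 else DEFAULT_DQ_OVER_Q * q

    name = meta.pop("name", meta.pop("contrast", path.stem))
    if "x_d2o" in meta:
        x = float(meta.pop("x_d2o"))
    else:
        x = _CONTRAST_PRESETS.get(name.lower(), 0.0)
    isotope = meta.pop("protein_isotope", "h")
    return ContrastDataset(
        q=q, r=r, dr=dr, dq=dq,
        contrast=SolventContrast(name, x),
        protein_isotope=isotope,
        metadata=meta,
    )


def write_reflectivity(dataset: ContrastDataset, path: str | Path) -> Path:
    """Write a dataset as 4-column ASCII with contrast metadata headers."""
    path = Path(path)
    header = [
        f"# name: {dataset.contrast.name}",
        f"# x_d2o: {dataset.contrast.x_d2o:.6g}",
        f"# protein_isotope: {dataset.protein_isotope}",
        "# columns: Q(1/A) R dR dQ(FWHM)",
    ]
    dq = dataset.dq if dataset.dq is not None else DEFAULT_DQ_OVER_Q * dataset.q
    body = "\n".join(
        f"{q:.8e} {r:.8e} {dr:.8e} {d:.8e}"
        for q, r, dr, d in zip(dataset.q, dataset.r, dataset.dr, dq)
    )
    path.write_text("\n".join(header) + "\n" + body + "\n")
    return path


def read_trace(path: str | Path) -> KineticTrace:
    """Read a kinetic trace from 3-4 column text (t, y, dy[, t_window])."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: expected >=3 columns (t y dy)")
    window = data[:, 3] if data.shape[1] >= 4 else None
    return KineticTrace(t=data[:, 0], y=data[:, 1], dy=data[:, 2], t_window=window)


def write_trace(trace: KineticTrace, path: str | Path) -> Path:
    path = Path(path)
    cols = [trace.t, trace.y, trace.dy]
    header = "t(min) y dy"
    if trace.t_window is not None:
        cols.append(trace.t_window)
        header += " t_window(min)"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.8e")
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "x_cl", "model", "fixture", "datasets", "free_params", "links",
    "seed", "n_steps", "de_maxiter", "noise", "n_q", "q_range",
    "contrasts", "protein_isotope", "output", "kinetics",
}

_DEFAULTS = {"seed": 0, "n_steps": 1000, "de_maxiter": 40, "protein_isotope": "h"}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run specification.

    Unknown top-level keys and inverted bounds are rejected; defaults
    (seed, chain length, optimizer budget) are applied and the final config
    is echoed to the log so every run is reproducible from the file alone.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    for name, bound in (cfg.get("free_params") or {}).items():
        lo, hi = bound
        if lo >= hi:
            raise ValueError(f"free_params[{name}]: bound low {lo} >= high {hi}")
    cfg["_config_hash"] = hashlib.sha256(path.read_bytes()).hexdigest()[:12]
    log.info("loaded config %s (sha %s): %s", path, cfg["_config_hash"], cfg)
    return cfg


# ---------------------------------------------------------------------------
# Reports and pipeline
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    return f"{value:.6g}"


def format_fit_report(result: FitResult) -> str:
    """Flat parameter table (parameter, best, median, low65, high65)."""
    lines = ["parameter\tbest\tmedian\tlow65\thigh65"]
    for name in result.param_names:
        lo, hi = result.ci65[name]
        lines.append(
            "\t".join(
                [
                    name,
                    _fmt(result.best_params[name]),
                    _fmt(result.median_params[name]),
                    _fmt(lo),
                    _fmt(hi),
                ]
            )
        )
    lines.append(f"# chi2\t{_fmt(result.chi2)}")
    if result.flat_posterior:
        lines.append("# warning: flat posterior (non-identifiable parameter)")
    return "\n".join(lines) + "\n"


def run_pipeline(subcommand: str, config: dict | str | Path, outdir: str | Path = ".") -> dict:
    """Execute one pipeline stage and write its artifacts.

    Subcommands: ``simulate`` (synthetic contrast sets from a fixture),
    ``fit`` (co-refinement of the configured datasets), ``kinetics``
    (biexponential fit of a trace file), ``balance`` (before/after poration
    summary) and ``report`` (collate fit tables).  Every run logs the seed
    and config hash; outputs are deterministic given (config, seed).
    """
    from . import synthetic
    from .inference import corefine
    from .kinetics import fit_biexponential
    from .poration import poration_summary

    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log.info("run_pipeline %s seed=%s hash=%s", subcommand, seed, config.get("_config_hash"))
    artifacts: dict = {"subcommand": subcommand, "outdir": str(outdir)}

    if subcommand == "simulate":
        catalog = synthetic.fixture_catalog()
        fixture = config.get("fixture", "10CL_before")
        model = catalog[fixture]
        datasets = synthetic.generate_contrast_set(
            model,
            noise=tuple(config.get("noise", synthetic.DEFAULT_NOISE)),
            n_q=int(config.get("n_q", synthetic.DEFAULT_N_Q)),
            seed=seed,
            protein_isotope=config.get("protein_isotope", "h"),
        )
        paths = []
        for ds in datasets:
            p = write_reflectivity(ds, outdir / f"{fixture}_{ds.contrast.name}.dat")
            paths.append(str(p))
        artifacts["datasets"] = paths

    elif subcommand == "fit":
        datasets = [read_reflectivity(p) for p in config["datasets"]]
        catalog = synthetic.fixture_catalog()
        model = catalog[config.get("fixture", "10CL_before")]
        result = corefine(
            model,
            datasets,
            {k: tuple(v) for k, v in config["free_params"].items()},
            seed=seed,
            n_steps=int(config.get("n_steps", 1000)),
            de_maxiter=int(config.get("de_maxiter", 40)),
        )
        table = format_fit_report(result)
        (outdir / "fit_report.tsv").write_text(table)
        np.save(outdir / "chain.npy", result.chain)
        artifacts["fit_report"] = str(outdir / "fit_report.tsv")
        artifacts["result"] = result

    elif subcommand == "kinetics":
        trace = read_trace(config["kinetics"]["trace"])
        fit = fit_biexponential(
            trace, seed=seed, n_exp=int(config["kinetics"].get("n_exp", 2))
        )
        report = {
            k: getattr(fit, k)
            for k in ("a_fast", "tau_fast", "a_slow", "tau_slow", "baseline", "chi2",
                      "converged", "degenerate")
        }
        (outdir / "kinetics.json").write_text(json.dumps(report, indent=2))
        artifacts["kinetics"] = report

    elif subcommand == "balance":
        before = config["model"]["before"]
        after = config["model"]["after"]
        summary = poration_summary(before, after, x_cl=float(config.get("x_cl", 0.1)),
                                   seed=seed)
        text = [
            f"x_cl\t{_fmt(summary.x_cl)}",
            f"coverage_before\t{_fmt(summary.coverage_before)}",
            f"coverage_after\t{_fmt(summary.coverage_after)}",
            f"lipid_removed\t{_fmt(summary.lipid_removed)}",
            f"thinning\t{_fmt(summary.thinning)}",
            f"complex_lipid\t{_fmt(summary.complex_lipid)}",
            f"complex_protein\t{_fmt(summary.complex_protein)}",
            f"balance_ratio\t{_fmt(summary.balance_ratio)}",
        ]
        (outdir / "poration_summary.tsv").write_text("\n".join(text) + "\n")
        artifacts["summary"] = summary

    elif subcommand == "report":
        tables = sorted(outdir.glob("*.tsv"))
        if not tables:
            raise FileNotFoundError(
                f"no fit tables found in {outdir}; run 'fit' or 'balance' first"
            )
        combined = "\n".join(p.read_text() for p in tables)
        (outdir / "report.txt").write_text(combined)
        artifacts["report"] = str(outdir / "report.txt")

    else:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    return artifacts
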