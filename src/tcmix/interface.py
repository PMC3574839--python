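"""File I/O, normalisation and the replicated simulation study.

All on-disk formats are plain tab-delimited text: an expression matrix has a
header row of numeric time values, one gene per row with its identifier in
the first column.  ``replicate_study`` reproduces one study table end to
end — generate replicates from a preset, fit the proposed model from the
true partition and the AR(1)-residual baseline from the true parameter
values, score both clusterings against the truth, and assemble the
mean/RMSE/SD/proportion-better footer together with parameter bias/RMSE
blocks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import __version__
from .baseline_kim import fit_kim, fit_kmeans_baseline
from .em_fit import FitResult, fit
from .evaluate import ReplicationSummary, compare_partitions, summarize_replicates
from .exceptions import InvalidParameterError, NormalizationError, TcmixError
from .model_core import MixtureModel, TimeCourseMatrix
from .simulate import SimulationConfig, generate, preset, replicate_seed

logger = logging.getLogger("tcmix")

__all__ = [
    "read_matrix",
    "write_matrix",
    "normalize_rows_columns",
    "replicate_study",
    "StudyResult",
    "write_fit_result",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path) -> TimeCourseMatrix:
    """Read a gene-by-time TSV matrix.

    The header row holds numeric time values (falls back to sequential
    indices if non-numeric); the first column holds gene identifiers.  Rows
    containing missing values are dropped with a logged count; duplicate gene
    identifiers are disambiguated with a numeric suffix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError:
        times = np.arange(df.shape[1], dtype=float)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad_cells = np.isnan(values) & df.notna().to_numpy()
    if bad_cells.any():
        r, c = np.argwhere(bad_cells)[0]
        raise InvalidParameterError(
            f"non-numeric cell at gene {df.index[r]!r}, column {df.columns[c]!r}"
        )
    keep = ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d genes with missing expression levels", n_dropped)
    ids = list(df.index[keep].astype(str))
    if len(set(ids)) < len(ids):
        logger.warning("duplicate gene identifiers found; adding suffixes")
        seen: dict[str, int] = {}
        out = []
        for gid in ids:
            seen[gid] = seen.get(gid, 0) + 1
            out.append(gid if seen[gid] == 1 else f"{gid}.{seen[gid]}")
        ids = out
    return TimeCourseMatrix(values=values[keep], times=times, gene_ids=ids)


def write_matrix(data: TimeCourseMatrix, path) -> None:
    df = pd.DataFrame(
        data.values,
        index=pd.Index(data.gene_ids, name="gene"),
        columns=[repr(float(t)) for t in data.times],
    )
    # shortest round-trip repr keeps the values bit-exact through text
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def normalize_rows_columns(data: TimeCourseMatrix, log_transform: bool = False) -> TimeCourseMatrix:
    """Optional log transform, then column standardisation, then row
    standardisation (mean 0, SD 1; population SD).  The column-then-row order
    is a fixed convention of this package."""
    values = data.values
    if log_transform:
        if np.any(values <= 0):
            raise NormalizationError("log transform requires strictly positive values")
        values = np.log(values)
    col_sd = values.std(axis=0)
    if np.any(col_sd == 0):
        raise NormalizationError("zero-variance column")
    values = (values - values.mean(axis=0)) / col_sd
    row_sd = values.std(axis=1, keepdims=True)
    if np.any(row_sd == 0):
        raise NormalizationError("zero-variance row")
    values = (values - values.mean(axis=1, keepdims=True)) / row_sd
    return TimeCourseMatrix(values=values, times=data.times, gene_ids=list(data.gene_ids))


# ---------------------------------------------------------------------------
# fit-result serialisation


def write_fit_result(result: FitResult, data: TimeCourseMatrix, outdir) -> None:
    """Write labels.tsv, posterior.tsv and model.txt for a fitted model."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = pd.DataFrame(
        {
            "gene": data.gene_ids,
            "label": result.labels,
            "max_posterior": result.tau[np.arange(data.n_genes), result.labels],
        }
    )
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    post = pd.DataFrame(
        result.tau,
        index=pd.Index(data.gene_ids, name="gene"),
        columns=[f"comp{h}" for h in range(result.tau.shape[1])],
    )
    post.to_csv(outdir / "posterior.tsv", sep="\t")
    (outdir / "model.txt").write_text(result.model.to_text())


def write_manifest(outdir, config: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "tcmix", "version": __version__, **config}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


# ---------------------------------------------------------------------------
# replicated simulation study

_PARAM_NAMES = ["p", "a0", "a1", "b1", "theta2", "rho", "sigma2", "d2"]


def _component_estimates(model: MixtureModel) -> np.ndarray:
    """(g x 8) array of per-component scalars in _PARAM_NAMES order."""
    rows = []
    for c in model.components:
        rows.append([c.weight_p, c.beta[0], c.beta[1], c.beta[2], c.theta2, c.rho, c.sigma2, c.d2])
    return np.asarray(rows)


def _align_to_truth(true_labels: np.ndarray, pred_labels: np.ndarray, g: int) -> np.ndarray:
    """perm[h] = fitted-component index matched to true component h."""
    confusion = np.zeros((g, g), dtype=np.int64)
    np.add.at(confusion, (true_labels, pred_labels), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    perm = np.empty(g, dtype=int)
    perm[rows] = cols
    return perm


@dataclass
class StudyResult:
    """Outcome of one replicated simulation table."""

    preset_id: str
    config: SimulationConfig
    metrics: pd.DataFrame  # per replicate x method x metric (long format)
    summaries: dict  # (metric, pair) -> ReplicationSummary
    bias: pd.DataFrame | None  # parameter bias/RMSE per method and component
    n_failed: int

    def mean_metric(self, method: str, metric: str) -> float:
        sel = self.metrics[self.metrics["method"] == method]
        return float(sel[metric].mean())

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for (metric, pair), s in self.summaries.items():
            rows.append(
                {
                    "metric": metric,
                    "comparison": pair,
                    "mean_a": s.method_a.mean,
                    "rmse_a": s.method_a.rmse,
                    "sd_a": s.method_a.sd,
                    "mean_b": s.method_b.mean if s.method_b else np.nan,
                    "rmse_b": s.method_b.rmse if s.method_b else np.nan,
                    "sd_b": s.method_b.sd if s.method_b else np.nan,
                    "proportion_a_better": s.proportion_better,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "replicates.tsv", sep="\t", index=False)
        self.summary_table().to_csv(outdir / "summary.tsv", sep="\t", index=False)
        if self.bias is not None:
            self.bias.to_csv(outdir / "bias.tsv", sep="\t", index=False)


def replicate_study(
    preset_id: str,
    n_replicates: int,
    seed: int,
    n_genes: int = 400,
    tol: float = 1e-5,
    max_iter: int = 1000,
    include_kmeans: bool = False,
    collect_bias: bool = True,
    kmeans_starts: int = 10,
) -> StudyResult:
    """Run one simulation table: generate replicates, fit both models, score.

    The proposed model is initialised at the true partition; the baseline at
    the true parameter values.  The win-proportion convention is strict
    ("better") under the full-model and independent-gene generators and
    non-strict ("not worse") under the baseline's own AR(1)-residual
    generator.  Replicates whose fits fail are logged and excluded.
    """
    config = preset(preset_id, n_genes=n_genes, seed=seed, n_replicates=n_replicates)
    g = config.g
    periods = np.asarray(config.periods)
    rows = []
    est_rows = {"emw": [], "kim": []}
    n_failed = 0
    for r in range(n_replicates):
        ds = generate(config, seed=replicate_seed(seed, r))
        try:
            emw = fit(
                ds.data, g, ds.true_model.design, init="true-partition",
                labels=ds.true_labels, periods=periods, tol=tol, max_iter=max_iter,
            )
            kim = fit_kim(
                ds.data, g, ds.true_model.design, init=ds.true_model,
                tol=tol, max_iter=max_iter,
            )
        except TcmixError as err:
            logger.warning("replicate %d failed: %s", r, err)
            n_failed += 1
            continue
        for method, res in (("emw", emw), ("kim", kim)):
            cmp_ = compare_partitions(ds.true_labels, res.labels)
            rows.append(
                {
                    "replicate": r,
                    "method": method,
                    "error_rate": cmp_.error_rate,
                    "rand": cmp_.rand,
                    "adjusted_rand": cmp_.adjusted_rand,
                }
            )
            if collect_bias:
                perm = _align_to_truth(ds.true_labels, res.labels, g)
                est_rows[method].append(_component_estimates(res.model)[perm])
        if include_kmeans:
            km_labels = fit_kmeans_baseline(ds.data, g, seed=r, n_starts=kmeans_starts)
            cmp_ = compare_partitions(ds.true_labels, km_labels)
            rows.append(
                {
                    "replicate": r,
                    "method": "kmeans",
                    "error_rate": cmp_.error_rate,
                    "rand": cmp_.rand,
                    "adjusted_rand": cmp_.adjusted_rand,
                }
            )
    metrics = pd.DataFrame(rows)

    strict = config.regime != "ar1-residual"
    summaries = {}
    emw_vals = metrics[metrics["method"] == "emw"].sort_values("replicate")
    kim_vals = metrics[metrics["method"] == "kim"].sort_values("replicate")
    for metric in ("error_rate", "rand", "adjusted_rand"):
        summaries[(metric, "emw_vs_kim")] = summarize_replicates(
            metric, emw_vals[metric].to_numpy(), kim_vals[metric].to_numpy(), strict=strict
        )
    if include_kmeans:
        km_vals = metrics[metrics["method"] == "kmeans"].sort_values("replicate")
        for metric in ("error_rate", "adjusted_rand"):
            summaries[(metric, "kmeans")] = summarize_replicates(metric, km_vals[metric].to_numpy())

    bias_df = None
    if collect_bias and est_rows["emw"]:
        truth = _component_estimates(config.true_model())
        bias_records = []
        for method, stack in est_rows.items():
            est = np.asarray(stack)  # (R, g, 8)
            n_params = 6 if method == "kim" else 8
            for h in range(g):
                for k in range(n_params):
                    err = est[:, h, k] - truth[h, k]
                    bias_records.append(
                        {
                            "method": method,
                            "component": h,
                            "parameter": _PARAM_NAMES[k],
                            "truth": truth[h, k],
                            "bias": float(err.mean()),
                            "rmse": float(np.sqrt((err**2).mean())),
                            "se": float(err.std(ddof=1) / np.sqrt(err.size))
                            if err.size > 1
                            else float("nan"),
                        }
                    )
        bias_df = pd.DataFrame(bias_records)

    return StudyResult(
        preset_id=preset_id,
        config=config,
        metrics=metrics,
        summaries=summaries,
        bias=bias_df,
        n_failed=n_failed,
    )
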