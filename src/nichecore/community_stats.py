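"""Community statistics: alpha diversity, Bray–Curtis dissimilarity, principal
coordinates, distance-based permutation tests (PERMANOVA / ANOSIM), ordinary
ANOVA-style models for diversity, and quasi-Poisson differential abundance.

All statistics are implemented directly from their definitions:

* PERMANOVA partitions the Gower-centered squared-distance matrix by
  sequential (Type-I) projections of the model terms, in the order given —
  the behaviour of ``adonis`` — with pseudo-F compared against free
  permutations of the sample labels.
* ANOSIM compares mean between-group and within-group distance ranks,
  ``R = (r̄_B - r̄_W) / (M/2)`` with ``M = n(n-1)/2``.
* Differential abundance fits a per-OTU log-linear model to the raw counts by
  iteratively reweighted least squares with a log library-size offset; the
  quasi-Poisson dispersion is the Pearson X² divided by the residual degrees
  of freedom, and model terms are tested with an F statistic
  ``(ΔDeviance/Δdf)/φ̂``, followed by Benjamini–Hochberg adjustment.

Permutation p-values use the add-one rule ``(1 + #{F* >= F}) / (1 + B)`` and
are exactly reproducible given a seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_tables import OtuTable, SampleMetadata, TableValidationError

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def richness(table: OtuTable, min_count: int = 1) -> pd.Series:
    """Observed OTU count per sample."""
    return table.presence(min_count=min_count).sum(axis=1).astype(np.int64)


def shannon(table: OtuTable) -> pd.Series:
    """Shannon index per sample, in nats: H = -sum p_i ln p_i over p_i > 0."""
    p = table.relative_abundance().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


# ---------------------------------------------------------------------------
# Bray–Curtis and PCoA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-10):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def bray_curtis(table: OtuTable, relative: bool = False) -> DistanceMatrix:
    """Bray–Curtis dissimilarity d(a,b) = sum|a_i-b_i| / sum(a_i+b_i).

    Computed on raw counts by default; set ``relative=True`` to compute on
    per-sample relative abundances (removes library-size signal).
    """
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least two samples")
    X = (
        table.relative_abundance().to_numpy()
        if relative
        else table.counts.to_numpy().astype(float)
    )
    sums = X.sum(axis=1)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        num = np.abs(X[i + 1 :] - X[i]).sum(axis=1)
        den = sums[i + 1 :] + sums[i]
        if np.any(den == 0):
            j = i + 1 + int(np.argmax(den == 0))
            raise ValueError(
                f"Bray-Curtis undefined for the all-zero sample pair "
                f"({table.sample_ids[i]!r}, {table.sample_ids[j]!r})"
            )
        d[i, i + 1 :] = d[i + 1 :, i] = num / den
    return DistanceMatrix(ids=tuple(table.sample_ids), values=d)


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Axes are eigenvectors of the Gower-centered squared-distance matrix,
    scaled by the square root of their (positive) eigenvalues. Negative
    eigenvalues — non-Euclidean residual structure of Bray–Curtis — are not
    corrected; their total magnitude is reported.
    """
    g = _gower_center(dm.values**2)
    eigvals, eigvecs = linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    total = lam.sum()
    return PcoaResult(
        coordinates=frame,
        eigenvalues=lam,
        proportion_explained=lam / total if total > 0 else np.zeros_like(lam),
        negative_eigenvalue_mass=float(-eigvals[eigvals < -tol].sum()),
    )


# ---------------------------------------------------------------------------
# Model-matrix construction (shared by PERMANOVA, diversity ANOVA, the GLM)
# ---------------------------------------------------------------------------


def _metadata_frame(metadata: SampleMetadata | pd.DataFrame, ids: Sequence[str]) -> pd.DataFrame:
    frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    missing = [s for s in ids if s not in frame.index]
    if missing:
        raise TableValidationError(f"samples without metadata records: {missing}")
    return frame.loc[list(ids)]


def _encode_column(values: pd.Series, term: str) -> np.ndarray:
    """Numeric column as-is; categorical as treatment-coded dummies."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)[:, None]
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has a single level ({levels[0]!r})")
    return np.column_stack(
        [(values.astype(str) == lvl).to_numpy(dtype=float) for lvl in levels[1:]]
    )


def design_blocks(
    frame: pd.DataFrame, terms: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    """One coded column block per term; ``A:B`` denotes an interaction."""
    blocks = []
    for term in terms:
        parts = term.split(":")
        coded = [
            _encode_column(frame[p], term) if p in frame.columns else _missing(p)
            for p in parts
        ]
        block = coded[0]
        for other in coded[1:]:
            block = np.einsum("ni,nj->nij", block, other).reshape(len(frame), -1)
        blocks.append((term, block))
    return blocks


def _missing(column: str):
    raise KeyError(f"metadata has no column {column!r}")


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    q = linalg.orth(X)
    return q


# ---------------------------------------------------------------------------
# PERMANOVA (ADONIS-style) and ANOSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    table: pd.DataFrame  # index: terms + Residual + Total
    n_permutations: int
    seed: int | None

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    Terms are fitted in the order given (Type-I); each term's SS is the trace
    of its incremental projection applied to the Gower-centered matrix.
    Labels are permuted freely; p-values use the add-one rule.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    frame = _metadata_frame(metadata, dm.ids)
    n = dm.n
    g = _gower_center(dm.values**2)
    ones = np.ones((n, 1))

    blocks = design_blocks(frame, terms)
    effects: list[np.ndarray] = []  # per-term incremental projector
    dfs: list[int] = []
    X = ones
    h_prev = np.ones((n, n)) / n
    for term, block in blocks:
        X = np.hstack([X, block])
        q = _orth(X)
        h = q @ q.T
        df = int(round(np.trace(h) - np.trace(h_prev)))
        if df < 1:
            raise ValueError(f"term {term!r} adds no degrees of freedom (aliased)")
        effects.append(h - h_prev)
        dfs.append(df)
        h_prev = h
    resid = np.eye(n) - h_prev
    df_res = int(round(np.trace(resid)))
    if df_res < 1:
        raise ValueError("saturated model: no residual degrees of freedom")

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([np.vdot(m, gmat) for m in effects])
        ss_res = float(np.vdot(resid, gmat))
        ms_res = ss_res / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.array(dfs)) / ms_res if ms_res > 0 else np.full(len(ss), np.inf)
        return f, ss_res

    f_obs, ss_res_obs = f_stats(g)
    ss_obs = np.array([np.vdot(m, g) for m in effects])
    ss_total = float(np.trace(g))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        f_perm, _ = f_stats(gp)
        exceed += f_perm >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)

    rows = {}
    for i, term in enumerate(terms):
        rows[term] = {
            "df": dfs[i],
            "sum_sq": ss_obs[i],
            "R2": ss_obs[i] / ss_total if ss_total > 0 else np.nan,
            "pseudo_F": f_obs[i],
            "p_value": p[i],
        }
    rows["Residual"] = {
        "df": df_res,
        "sum_sq": ss_res_obs,
        "R2": ss_res_obs / ss_total if ss_total > 0 else np.nan,
        "pseudo_F": np.nan,
        "p_value": np.nan,
    }
    rows["Total"] = {
        "df": n - 1,
        "sum_sq": ss_total,
        "R2": 1.0,
        "pseudo_F": np.nan,
        "p_value": np.nan,
    }
    return PermanovaResult(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def anosim(
    dm: DistanceMatrix,
    grouping: Sequence[str] | pd.Series | Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Rank-based analysis of similarity across >= 2 groups."""
    if isinstance(grouping, Mapping):
        groups = np.array([str(grouping[s]) for s in dm.ids])
    elif isinstance(grouping, pd.Series):
        groups = grouping.loc[list(dm.ids)].astype(str).to_numpy()
    else:
        groups = np.asarray([str(g) for g in grouping])
        if len(groups) != dm.n:
            raise ValueError("grouping length must match the distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; offending: {small}")

    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.values[iu])
    m = n * (n - 1) // 2

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2))

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r_stat(groups[rng.permutation(n)]) >= r_obs - 1e-12:
            exceed += 1
    return AnosimResult(
        r=r_obs, p_value=(1 + exceed) / (1 + n_perm), n_permutations=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# Diversity ANOVA / regression (sequential OLS)
# ---------------------------------------------------------------------------


def diversity_model(
    diversity: pd.Series,
    metadata: SampleMetadata | pd.DataFrame,
    terms: Sequence[str] = ("Niche", "Depth"),
) -> pd.DataFrame:
    """Ordinary least squares of a per-sample diversity measure on metadata
    terms, with sequential (Type-I) F tests.

    Returns a table indexed by term (+ Residual) with df, sum_sq, mean_sq, F
    and p. A rank-deficient design raises, naming the aliased term.
    """
    y = diversity.astype(float)
    frame = _metadata_frame(metadata, list(y.index))
    n = len(y)
    yv = y.to_numpy()

    blocks = design_blocks(frame, terms)
    X = np.ones((n, 1))
    rss_prev = float(np.sum((yv - yv.mean()) ** 2))
    rank_prev = 1
    rows: dict[str, dict] = {}
    seq: list[tuple[str, int, float]] = []
    for term, block in blocks:
        X = np.hstack([X, block])
        q = _orth(X)
        rank = q.shape[1]
        df = rank - rank_prev
        if df < 1:
            raise ValueError(
                f"rank-deficient design: term {term!r} is aliased with earlier terms"
            )
        fitted = q @ (q.T @ yv)
        rss = float(np.sum((yv - fitted) ** 2))
        seq.append((term, df, rss_prev - rss))
        rss_prev, rank_prev = rss, rank
    df_res = n - rank_prev
    if df_res < 1:
        raise ValueError("saturated model: no residual degrees of freedom")
    mse = rss_prev / df_res
    for term, df, ss in seq:
        ms = ss / df
        if ss <= _EPS and mse <= _EPS:
            f, p = 0.0, 1.0
        elif mse <= _EPS:
            f, p = np.inf, 0.0
        else:
            f = ms / mse
            p = float(stats.f.sf(f, df, df_res))
        rows[term] = {"df": df, "sum_sq": ss, "mean_sq": ms, "F": f, "p_value": p}
    rows["Residual"] = {
        "df": df_res,
        "sum_sq": rss_prev,
        "mean_sq": mse,
        "F": np.nan,
        "p_value": np.nan,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Quasi-Poisson differential abundance
# ---------------------------------------------------------------------------


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    return float(2.0 * terms.sum())


def _irls_poisson(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit log mu = X beta + offset by iteratively reweighted least squares."""
    mu = np.maximum(y, 0.0) + np.mean(y) / 2 + 0.1
    eta = np.log(mu) - offset
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta + offset)
        dev_new = _poisson_deviance(y, mu)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            return beta, mu, dev_new, True
        dev = dev_new
    return beta, mu, dev, False


@dataclass(frozen=True)
class DiffAbundanceResult:
    table: pd.DataFrame  # per-OTU statistics
    terms: tuple[str, ...]
    coef_names: tuple[str, ...]

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        ok = self.table["status"] == "ok"
        return self.table[ok & (self.table["q_value"] <= q_max)]


def diff_abundance(
    table: OtuTable,
    metadata: SampleMetadata | pd.DataFrame,
    terms: Sequence[str] = ("Niche",),
    dispersion: float | None = None,
) -> DiffAbundanceResult:
    """Per-OTU quasi-Poisson regression of counts on metadata terms.

    Each OTU's counts are modeled with a log link and a log library-size
    offset. The model-vs-intercept F test uses the estimated dispersion
    (Pearson X² / residual df), or a fixed ``dispersion`` when given (1.0
    recovers ordinary Poisson deviance testing). q-values are BH-adjusted
    across the OTUs that were actually fitted; all-zero or non-converged
    OTUs are flagged and excluded from the adjustment.
    """
    frame = _metadata_frame(metadata, table.sample_ids)
    sizes = table.library_sizes.to_numpy(dtype=float)
    if np.any(sizes <= 0):
        raise TableValidationError("all samples must have positive library size")
    offset = np.log(sizes)
    n = table.n_samples

    blocks = design_blocks(frame, terms)
    X_full = np.hstack([np.ones((n, 1))] + [b for _, b in blocks])
    coef_names = ["intercept"]
    for term, block in blocks:
        values = frame[term] if term in frame.columns else None
        if values is not None and not pd.api.types.is_numeric_dtype(values):
            levels = sorted(pd.unique(values.astype(str)))[1:]
            coef_names.extend(f"{term}[{lvl}]" for lvl in levels)
        elif block.shape[1] == 1:
            coef_names.append(term)
        else:
            coef_names.extend(f"{term}[{i}]" for i in range(block.shape[1]))
    p_full = np.linalg.matrix_rank(X_full)
    if p_full < X_full.shape[1]:
        raise ValueError("rank-deficient design for diff_abundance")
    df_num = p_full - 1
    df_den = n - p_full
    if df_den < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    X_null = np.ones((n, 1))

    counts = table.counts.to_numpy(dtype=float)
    records = []
    for j, otu in enumerate(table.otu_ids):
        y = counts[:, j]
        rec: dict = {"otu_id": otu}
        if y.sum() == 0:
            rec.update(status="all_zero", F=np.nan, p_value=np.nan, dispersion=np.nan)
            records.append(rec)
            continue
        beta1, mu1, dev1, conv1 = _irls_poisson(y, X_full, offset)
        beta0, mu0, dev0, conv0 = _irls_poisson(y, X_null, offset)
        if not (conv1 and conv0):
            rec.update(status="not_converged", F=np.nan, p_value=np.nan, dispersion=np.nan)
            records.append(rec)
            continue
        pearson = float(np.sum((y - mu1) ** 2 / mu1))
        phi = dispersion if dispersion is not None else pearson / df_den
        delta_dev = max(dev0 - dev1, 0.0)
        if delta_dev <= 1e-10:
            f_stat, p = 0.0, 1.0
        elif phi <= _EPS:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (delta_dev / df_num) / phi
            p = float(stats.f.sf(f_stat, df_num, df_den))
        rec.update(status="ok", F=f_stat, p_value=p, dispersion=phi, deviance=dev1)
        for name, b in zip(coef_names[1:], beta1[1:]):
            rec[f"rate_ratio[{name}]"] = float(np.exp(b))
        records.append(rec)

    result = pd.DataFrame.from_records(records).set_index("otu_id")
    result["q_value"] = np.nan
    ok = result["status"] == "ok"
    if ok.any():
        result.loc[ok, "q_value"] = bh_adjust(result.loc[ok, "p_value"].to_numpy())
    return DiffAbundanceResult(
        table=result, terms=tuple(terms), coef_names=tuple(coef_names)
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
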