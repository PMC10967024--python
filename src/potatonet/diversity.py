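"""Rarefaction, alpha diversity, Bray-Curtis/PCoA, PERMANOVA, vector fitting
and location-centered constrained RDA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables_io import CountTable, SampleFrame

FACTOR_ALIASES = {"time": "timepoint"}


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionResult:
    table: CountTable
    dropped: list[str]  # sample ids below depth


def rarefy(table: CountTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample without replacement to exactly `depth` reads.

    Samples with fewer than `depth` total reads are dropped and reported.
    Deterministic under `seed`.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep, dropped, rows = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        keep.append(sid)
        if totals[i] == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    if not keep:
        raise ValueError("all samples below depth")
    out = CountTable(keep, list(table.taxon_ids), np.vstack(rows), table.marker)
    return RarefactionResult(out, dropped)


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness of a without-replacement subsample."""
    from scipy.special import gammaln

    counts = np.asarray(counts)
    n = counts.sum()
    if depth > n:
        raise ValueError("depth exceeds sample total")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for c in counts[counts > 0]:
        if n - c >= depth:
            p_absent = np.exp(log_comb(n - c, depth) - log_comb(n, depth))
        else:
            p_absent = 0.0
        total += 1.0 - p_absent
    return total


def rarefaction_curve(
    table: CountTable, depths: list[int], n_draws: int, seed: int
) -> pd.DataFrame:
    """Mean richness and Shannon per sample at each depth over repeated draws.

    Samples with total below a depth carry NaN at that depth.
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be increasing")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    records = []
    for i, sid in enumerate(table.sample_ids):
        for depth in depths:
            if totals[i] < depth:
                records.append((sid, depth, np.nan, np.nan))
                continue
            rich = np.empty(n_draws)
            shan = np.empty(n_draws)
            for d in range(n_draws):
                sub = (
                    table.counts[i]
                    if totals[i] == depth
                    else rng.multivariate_hypergeometric(table.counts[i], depth)
                )
                nz = sub[sub > 0]
                rich[d] = nz.size
                p = nz / depth
                shan[d] = -np.sum(p * np.log(p))
            records.append((sid, depth, rich.mean(), shan.mean()))
    return pd.DataFrame(records, columns=["sample_id", "depth", "richness", "shannon"])


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha(table: CountTable) -> pd.DataFrame:
    """Observed richness, bias-corrected Chao1 and Shannon (natural log) per
    sample. Empty samples get NaN throughout."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        total = c.sum()
        if total == 0:
            rows.append((sid, np.nan, np.nan, np.nan))
            continue
        nz = c[c > 0]
        s_obs = nz.size
        f1 = int((nz == 1).sum())
        f2 = int((nz == 2).sum())
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = nz / total
        shannon = -np.sum(p * np.log(p))
        rows.append((sid, float(s_obs), chao1, shannon))
    return pd.DataFrame(
        rows, columns=["sample_id", "observed_richness", "chao1", "shannon"]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Bray-Curtis distances on relative abundances (sample-total invariant)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = table.relative_abundance()
    dm = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(distances: pd.DataFrame, atol: float = 1e-8) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Negative eigenvalues are reported but excluded from the coordinate space
    and the variance fractions.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(d - d.T)) > atol:
        raise ValueError("distance matrix not symmetric")
    g = _gower_center(d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(atol, atol * np.abs(evals).max())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum()
    return OrdinationResult(
        pd.DataFrame(coords, index=distances.index, columns=axes), evals, prop
    )


# ---------------------------------------------------------------------------
# design matrices for PERMANOVA / RDA
# ---------------------------------------------------------------------------

def _term_matrix(frame: SampleFrame, term: str, sample_ids: list[str]) -> np.ndarray:
    """Columns for one model term: factor dummies, numeric column, or an
    interaction given as 'a:b'."""
    data = frame.data.loc[sample_ids]
    parts = [FACTOR_ALIASES.get(p, p) for p in term.split(":")]
    mats = []
    for p in parts:
        if p not in data.columns:
            raise ValueError(f"unknown term component '{p}'")
        col = data[p]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)[:, None]
        else:
            levels = sorted(col.unique())
            if len(levels) < 2:
                raise ValueError(f"term '{p}' has a single level")
            v = np.column_stack([(col == lv).to_numpy(float) for lv in levels])
        mats.append(v)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = diag > tol
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _sequential_hats(
    frame: SampleFrame, terms: list[str], sample_ids: list[str]
) -> tuple[list[np.ndarray], list[int]]:
    n = len(sample_ids)
    x = np.ones((n, 1))
    hats, dfs = [], []
    h_prev, rank_prev = _hat(x), 1
    for term in terms:
        x = np.column_stack([x, _term_matrix(frame, term, sample_ids)])
        h, rank = _hat(x)
        hats.append(h)
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    return hats, dfs


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index terms + 'Residual'; columns df, SS, R2_pct, F, p


def permanova(
    distances: pd.DataFrame,
    frame: SampleFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) distance-based multivariate ANOVA.

    Terms are partitioned in the given order; p-values come from free
    permutation of sample labels, or within-`strata` permutation when a
    stratifying column is named.
    """
    sample_ids = list(distances.index)
    d = np.asarray(distances, dtype=float)
    g = _gower_center(d)
    n = len(sample_ids)
    hats, dfs = _sequential_hats(frame, terms, sample_ids)
    ss_total = float(np.trace(g))

    def term_ss(gm: np.ndarray) -> np.ndarray:
        fitted = np.array([float(np.sum(h * gm)) for h in hats])  # tr(H G), H symmetric
        return np.diff(np.concatenate([[0.0], fitted]))

    ss = term_ss(g)
    ss_res = ss_total - ss.sum()
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss / np.array(dfs)) / (ss_res / df_res)
    f_obs = np.where(np.isnan(f_obs), np.inf, f_obs)

    rng = np.random.default_rng(seed)
    if strata is not None:
        groups = frame.data.loc[sample_ids, strata].to_numpy()
        group_idx = [np.flatnonzero(groups == gl) for gl in pd.unique(groups)]

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for gi in group_idx:
                perm[gi] = gi[rng.permutation(len(gi))]
        gp = g[np.ix_(perm, perm)]
        ssp = term_ss(gp)
        ssp_res = ss_total - ssp.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = (ssp / np.array(dfs)) / (ssp_res / df_res)
        fp = np.where(np.isnan(fp), np.inf, fp)
        exceed += fp >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for t, df_t, ss_t, f_t, p_t in zip(terms, dfs, ss, f_obs, pvals):
        rows.append((t, df_t, ss_t, 100.0 * ss_t / ss_total, f_t, p_t))
    rows.append(("Residual", df_res, ss_res, 100.0 * ss_res / ss_total, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["term", "df", "SS", "R2_pct", "F", "p"]
    ).set_index("term")
    return PermanovaResult(out)


# ---------------------------------------------------------------------------
# envfit-style vector fitting
# ---------------------------------------------------------------------------

def fit_vectors(
    ordination: OrdinationResult,
    frame: SampleFrame,
    variables: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """R-squared of each numeric variable against the first two ordination
    axes; p-values by permuting the variable over complete cases."""
    coords = ordination.coordinates.iloc[:, :2]
    if coords.shape[1] < 2:
        raise ValueError("ordination has fewer than 2 axes")
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        v = frame.data.loc[coords.index, var].astype(float)
        mask = v.notna().to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"variable '{var}' has fewer than 3 complete samples")
        y = v.to_numpy()[mask]
        if np.allclose(y, y[0]):
            raise ValueError(f"variable '{var}' is constant")
        x = np.column_stack([np.ones(mask.sum()), coords.to_numpy()[mask]])

        def r2(yv: np.ndarray) -> float:
            beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
            resid = yv - x @ beta
            tot = np.sum((yv - yv.mean()) ** 2)
            return 1.0 - np.sum(resid ** 2) / tot

        obs = r2(y)
        exceed = sum(r2(rng.permutation(y)) >= obs for _ in range(n_perm))
        rows.append((var, int(mask.sum()), obs, (1.0 + exceed) / (1.0 + n_perm)))
    return pd.DataFrame(rows, columns=["variable", "n", "R2", "p"]).set_index("variable")


# ---------------------------------------------------------------------------
# location-centered constrained RDA
# ---------------------------------------------------------------------------

def rda_location_centered(
    table: CountTable,
    frame: SampleFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential RDA of log(1+count) community data centered per location.

    Per-term variance explained is the sequential fitted trace share; p-values
    permute residuals of the reduced model (Freedman-Lane).
    """
    sample_ids = list(table.sample_ids)
    y = np.log1p(table.counts.astype(float))
    loc = frame.data.loc[sample_ids, "location"].to_numpy()
    for lv in pd.unique(loc):
        idx = loc == lv
        y[idx] -= y[idx].mean(axis=0)

    hats, dfs = _sequential_hats(frame, terms, sample_ids)
    n = len(sample_ids)
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("singular design: no residual degrees of freedom")
    ss_total = float(np.sum(y ** 2))
    if ss_total == 0:
        # centering removed all variation; nothing to test
        return pd.DataFrame(
            {"df": dfs, "SS": 0.0, "R2_pct": 0.0, "F": np.nan, "p": np.nan},
            index=pd.Index(terms, name="term"),
        )

    cum_df = np.cumsum(dfs)

    def seq_f(ym: np.ndarray, j: int) -> float:
        """F of term j against the residual of the model up to term j."""
        fit_full = float(np.sum((hats[j] @ ym) * ym))
        fit_red = float(np.sum((hats[j - 1] @ ym) * ym)) if j > 0 else 0.0
        ss_j = fit_full - fit_red
        ss_r = float(np.sum(ym ** 2)) - fit_full
        df_r = n - 1 - cum_df[j]
        if df_r <= 0 or ss_r <= 0:
            return np.inf
        return (ss_j / dfs[j]) / (ss_r / df_r)

    fitted = np.array([float(np.sum((h @ y) * y)) for h in hats])  # tr(Y' H Y)
    ss = np.diff(np.concatenate([[0.0], fitted]))
    f_obs = np.array([seq_f(y, j) for j in range(len(terms))])

    # Freedman-Lane with permutation restricted to location blocks: after
    # per-location centering, rows are exchangeable only within a location
    rng = np.random.default_rng(seed)
    loc_blocks = [np.flatnonzero(loc == lv) for lv in pd.unique(loc)]

    def block_perm() -> np.ndarray:
        perm = np.arange(n)
        for blk in loc_blocks:
            perm[blk] = blk[rng.permutation(len(blk))]
        return perm

    exceed = np.zeros(len(terms))
    for j in range(len(terms)):
        base = hats[j - 1] @ y if j > 0 else np.zeros_like(y)
        resid = y - base
        for _ in range(n_perm):
            yp = base + resid[block_perm()]
            if seq_f(yp, j) >= f_obs[j]:
                exceed[j] += 1
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    return pd.DataFrame(
        {
            "df": dfs,
            "SS": ss,
            "R2_pct": 100.0 * ss / ss_total,
            "F": f_obs,
            "p": pvals,
        },
        index=pd.Index(terms, name="term"),
    )
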