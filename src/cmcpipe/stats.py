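"""Multivariate group statistics on CMC profiles.

A CMC profile is the six-dimensional vector of coherence values between three
EEG electrodes (central, Cz, frontal) and two EMG electrodes of one muscle set
(trunk or leg), per participant x task x frequency band x direction.  Profiles
are compared with the altGower dissimilarity (mean absolute difference across
the six dimensions, no range normalisation) and tested with a permutational
multivariate analysis of variance (PERMANOVA).

The PERMANOVA is the distance-based sum-of-squares partitioning of McArdle &
Anderson: with A = -D**2/2 Gower-centred to G, the sequential (type-I) sum of
squares of each model term is tr((H_t - H_{t-1}) G) for the accumulated hat
matrices H, and pseudo-F ratios each term's mean square against the residual
mean square.  P-values come from a seeded permutation null with
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

Repeated measures are honoured through the permutation scheme rather than an
explicit random-effect term: observations belonging to one participant stay
together.  For a term whose factors are constant within participants (the
group effect), entire participant blocks are exchanged; for terms involving
within-participant factors (task, band and their interactions), observations
are permuted within each participant.  Permuting within participants cannot
alter a between-participant factor, so block exchange is the only permutation
scheme under which the group test has power; this is the standard
exchangeable-units argument for repeated-measures PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermanovaResult",
    "assemble_profiles",
    "alt_gower_distance",
    "permanova",
    "pairwise_group_by_task",
    "nmds",
    "DEFAULT_TERMS",
]

#: Term order mirroring the published table layout.
DEFAULT_TERMS = (
    "band",
    "task",
    "group",
    "band:task",
    "band:group",
    "task:group",
    "band:task:group",
)


@dataclass
class PermanovaResult:
    term: str
    df: int
    ss: float
    pseudo_F: float
    p_value: float
    n_perm: int


# ---------------------------------------------------------------------------
# profile assembly and distances
# ---------------------------------------------------------------------------

def assemble_profiles(
    cmc_table: pd.DataFrame,
    mask: pd.DataFrame | None = None,
    index_cols: tuple[str, ...] = ("participant", "group", "task", "band", "direction", "muscle_set"),
) -> pd.DataFrame:
    """Average retained trials into per-cell six-dimensional CMC profiles.

    ``cmc_table`` is tidy with one row per trial x electrode pair, columns
    including ``index_cols``, 'trial', 'pair' and 'cmc'.  ``mask`` (optional)
    is merged on its shared columns and rows with retained == False are
    dropped.  The result has one row per cell with one column per pair; cells
    where some pair has no retained trial are flagged incomplete rather than
    fatal.
    """
    df = cmc_table.copy()
    all_pairs = list(pd.unique(df["pair"]))
    if mask is not None:
        key = [c for c in mask.columns if c in df.columns and c != "retained"]
        df = df.merge(mask[key + ["retained"]], on=key, how="left")
        df = df[df["retained"].fillna(False)]
    if df.empty:
        return pd.DataFrame()
    grouped = (
        df.groupby([*index_cols, "pair"], sort=False)["cmc"]
        .agg(["mean", "size"])
        .reset_index()
    )
    wide = grouped.pivot_table(
        index=list(index_cols), columns="pair", values="mean"
    )
    # a pair whose every trial was masked must surface as missing, not vanish
    wide = wide.reindex(columns=all_pairs).reset_index()
    wide.columns.name = None
    wide["complete"] = wide[all_pairs].notna().all(axis=1)
    return wide


def alt_gower_distance(profiles) -> np.ndarray:
    """altGower dissimilarity: mean absolute difference across dimensions.

    ``profiles`` is an (n, p) array or a DataFrame whose numeric columns are
    the profile dimensions.  Returns the symmetric (n, n) matrix.
    """
    if isinstance(profiles, pd.DataFrame):
        x = profiles.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("profiles must be a 2-D table of profile dimensions")
    if np.isnan(x).any():
        raise ValueError("profiles contain missing values; drop incomplete rows first")
    return squareform(pdist(x, metric="cityblock") / x.shape[1])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    cols = None
    for factor in term.split(":"):
        if factor not in design.columns:
            raise ValueError(f"design table lacks factor {factor!r}")
        dummies = pd.get_dummies(
            design[factor].astype("category"), drop_first=True
        ).to_numpy(dtype=float)
        if cols is None:
            cols = dummies
        else:
            cols = np.einsum("ij,ik->ijk", cols, dummies).reshape(len(design), -1)
    return cols


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1e-300)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _block_indices(design: pd.DataFrame, strata: str) -> list[np.ndarray]:
    codes = design[strata].to_numpy()
    order = {}
    for i, c in enumerate(codes):
        order.setdefault(c, []).append(i)
    return [np.asarray(v) for v in order.values()]


def _perm_indices(
    rng: np.random.Generator,
    n: int,
    blocks: list[np.ndarray] | None,
    exchange_blocks: bool,
) -> np.ndarray:
    if blocks is None:
        return rng.permutation(n)
    p = np.arange(n)
    if exchange_blocks:
        sizes = {len(b) for b in blocks}
        if len(sizes) != 1:
            raise ValueError(
                "block exchange requires equal-sized participant strata; "
                f"got sizes {sorted(len(b) for b in blocks)}"
            )
        order = rng.permutation(len(blocks))
        for i, j in enumerate(order):
            p[blocks[i]] = blocks[j]
    else:
        for b in blocks:
            p[b] = b[rng.permutation(len(b))]
    return p


def permanova(
    dist: np.ndarray,
    design: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    strata: str | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-factor PERMANOVA with sequential sums of squares.

    ``design`` has one row per observation (aligned with ``dist``) and one
    column per factor; ``strata`` names the participant column for
    repeated-measures permutation (see module docstring).  Returns one row per
    term with df, SS, pseudo-F and the permutation p-value.
    """
    g = _gower_center(dist)
    n = g.shape[0]
    if len(design) != n:
        raise ValueError("design table must align with the distance matrix")
    design = design.reset_index(drop=True)

    x = np.ones((n, 1))
    h_prev, rank_prev = _hat(x)
    delta_hats: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _term_matrix(design, term)])
        h, rank = _hat(x)
        df_t = rank - rank_prev
        if df_t == 0:
            raise ValueError(
                f"term {term!r} adds no estimable contrast (singular or empty cell)"
            )
        delta_hats.append(h - h_prev)
        dfs.append(df_t)
        h_prev, rank_prev = h, rank
    h_full, rank_full = h_prev, rank_prev
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    # tr(H_intercept G) = 0 because G is doubly centred, so the residual is
    # simply tr(G) - tr(H_full G).
    trace_g = float(np.trace(g))
    ss_terms = np.array([float(np.sum(dh * g)) for dh in delta_hats])
    ss_res = trace_g - float(np.sum(h_full * g))
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    blocks = _block_indices(design, strata) if strata is not None else None
    rng = np.random.default_rng(seed)
    rows = []
    for t_idx, term in enumerate(terms):
        if blocks is not None:
            factors = term.split(":")
            exchange = all(
                design.groupby(strata)[f].nunique().max() == 1 for f in factors
            )
        else:
            exchange = False
        perms = np.stack(
            [_perm_indices(rng, n, blocks, exchange) for _ in range(n_perm)]
        )
        count = 0
        chunk = max(1, int(4_000_000 // (n * n)))
        for s in range(0, n_perm, chunk):
            p = perms[s : s + chunk]
            gp = g[p[:, :, None], p[:, None, :]]
            ss_t = np.einsum("ij,pij->p", delta_hats[t_idx], gp)
            ss_r = trace_g - np.einsum("ij,pij->p", h_full, gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_t / dfs[t_idx]) * (df_res / ss_r)
            f_p = np.where(ss_r > 0, f_p, np.inf)
            count += int(np.sum(f_p >= f_obs[t_idx] - 1e-12))
        rows.append(
            {
                "term": term,
                "df": dfs[t_idx],
                "ss": ss_terms[t_idx],
                "pseudo_F": f_obs[t_idx],
                "p_value": (1 + count) / (1 + n_perm),
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)


def pairwise_group_by_task(
    dist: np.ndarray,
    design: pd.DataFrame,
    group_col: str = "group",
    task_col: str = "task",
    strata: str | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group contrast within each task level (no multiplicity adjustment)."""
    design = design.reset_index(drop=True)
    rows = []
    for k, task in enumerate(pd.unique(design[task_col])):
        sel = np.flatnonzero((design[task_col] == task).to_numpy())
        sub_design = design.iloc[sel].reset_index(drop=True)
        if sub_design[group_col].nunique() < 2:
            raise ValueError(f"task {task!r} contains a single group level")
        sub = dist[np.ix_(sel, sel)]
        res = permanova(
            sub, sub_design, terms=(group_col,), strata=strata,
            n_perm=n_perm, seed=seed + k,
        )
        rows.append(
            {
                "task": task,
                "df": int(res["df"].iloc[0]),
                "pseudo_F": float(res["pseudo_F"].iloc[0]),
                "p_value": float(res["p_value"].iloc[0]),
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def nmds(
    dist: np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Nonmetric multidimensional scaling (Kruskal stress-1, monotone
    regression on distance ranks, best of ``n_restarts`` seeded starts).

    Returns (coordinates, stress); the embedding is determined only up to
    rotation, reflection and scale.
    """
    dist = np.asarray(dist, dtype=float)
    from sklearn.manifold import MDS

    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=1e-12,
        random_state=int(seed) % (2**32),
        normalized_stress=True,
    )
    coords = mds.fit_transform(dist)
    return coords, float(mds.stress_)
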