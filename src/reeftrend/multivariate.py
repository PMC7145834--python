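"""Community-structure analysis: Bray-Curtis resemblance and nested PERMANOVA.

Densities are log(x+1) transformed, a dummy taxon at a fixed value is
appended so depauperate samples have a defined dissimilarity, and pairwise
Bray-Curtis dissimilarities (0-100 scale) feed a distance-based permutational
ANOVA with the study's three-factor hierarchical design: year (fixed) with
month nested in year and site nested in month nested in year (both random),
plus z-scored depth and longitude covariates entered first.

The partitioning uses the Gower-centred inner-product matrix
``G = J(-D^2/2)J`` and sequential (order-of-entry) sums of squares obtained
by projecting onto successively orthogonalised design sub-spaces;
``tr(P G)`` generalises the usual ANOVA sums of squares to arbitrary
(semi-metric) dissimilarities.  Pseudo-F denominators follow
expected-mean-square rules for the mixed nested design, and p-values come
from Freedman-Lane permutation of reduced-model residuals (the reduced model
holds every other term, so nested random structure is removed before
residuals are shuffled).  Exact enumeration replaces random permutations
when the permutation space is small.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .survey_io import CommunityMatrix, zscored_covariates
from .synthetic import year_bin_order

logger = logging.getLogger("reeftrend")

DEFAULT_N_PERM = 9999
MAX_EXACT_PERMUTATIONS = 20_000

#: pseudo-F denominator for each default term (expected-mean-squares rules)
DEFAULT_DENOMINATORS = {
    "Depth": "Residual",
    "Longitude": "Residual",
    "Year": "Month/Year",
    "Month/Year": "Site/Month/Year",
    "Site/Month/Year": "Residual",
}


# ---------------------------------------------------------------------------
# transformation & resemblance
# ---------------------------------------------------------------------------

def transform_log1p(matrix: CommunityMatrix) -> CommunityMatrix:
    """Return a copy of the matrix with every density x replaced by ln(x+1)."""
    x = matrix.densities.to_numpy()
    if (x < 0).any():
        raise ValueError("negative densities passed to log(x+1) transform")
    out = matrix.copy_with(pd.DataFrame(np.log1p(x), index=matrix.densities.index,
                                        columns=matrix.densities.columns))
    out.density_unit = f"log(1 + {matrix.density_unit})"
    return out


@dataclass
class ResemblanceMatrix:
    """Symmetric pairwise Bray-Curtis dissimilarities on the 0-100 scale."""

    values: np.ndarray
    ids: list
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("resemblance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("resemblance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-10:
            raise ValueError("resemblance diagonal must be zero")
        if v.min() < -1e-10 or v.max() > 100 + 1e-10:
            raise ValueError("dissimilarities must lie in [0, 100]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, meta: pd.DataFrame) -> "ResemblanceMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(values=df.to_numpy(), ids=list(df.index),
                   meta=meta.loc[df.index])


def bray_curtis(matrix: CommunityMatrix,
                dummy_density: float | None = 1.0) -> ResemblanceMatrix:
    """Bray-Curtis dissimilarity (x100) with an optional dummy taxon.

    ``d(a,b) = 100 * sum|a_i - b_i| / sum(a_i + b_i)`` over taxa including
    the dummy.  The dummy is appended at ``dummy_density`` to every sample
    after any transformation, so two empty samples have d = 0 instead of an
    undefined value.  With ``dummy_density=None`` no dummy is added and an
    all-zero sample raises.
    """
    x = matrix.densities.to_numpy(dtype=float)
    if dummy_density is not None:
        if dummy_density <= 0:
            raise ValueError("dummy_density must be positive (or None)")
        x = np.column_stack([x, np.full(len(x), float(dummy_density))])
    elif (x.sum(axis=1) == 0).any():
        bad = matrix.densities.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero samples undefined without a dummy taxon: {bad}")
    d = squareform(pdist(x, metric="braycurtis")) * 100.0
    return ResemblanceMatrix(values=d, ids=list(matrix.densities.index),
                             meta=matrix.meta.copy())


def mean_dissimilarities(res: ResemblanceMatrix, labels: pd.Series) -> pd.DataFrame:
    """Square table of mean dissimilarities: within-group on the diagonal,
    between-group off it."""
    labels = pd.Series(labels, index=res.ids)
    groups = year_bin_order(labels.unique())
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    idx = {g: np.flatnonzero((labels == g).to_numpy()) for g in groups}
    for i, g in enumerate(groups):
        ii = idx[g]
        if len(ii) > 1:
            block = res.values[np.ix_(ii, ii)]
            out.loc[g, g] = block[np.triu_indices(len(ii), k=1)].mean()
        for h in groups[i + 1:]:
            jj = idx[h]
            m = res.values[np.ix_(ii, jj)].mean()
            out.loc[g, h] = out.loc[h, g] = m
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def default_terms(meta: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    """Ordered design terms for the study model (covariates entered first)."""
    z = zscored_covariates(meta)
    ym = meta["year_bin"].astype(str) + "/" + meta["month"].astype(str)
    sym = meta["site"].astype(str) + "/" + ym
    return [
        ("Depth", z["depth_z"].to_numpy()[:, None]),
        ("Longitude", z["lon_z"].to_numpy()[:, None]),
        ("Year", _dummies(meta["year_bin"])),
        ("Month/Year", _dummies(ym)),
        ("Site/Month/Year", _dummies(sym)),
    ]


def _orth_increment(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the span of X beyond the span of Q."""
    Xr = X - Q @ (Q.T @ X)
    u, s, _ = np.linalg.svd(Xr, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    keep = s > max(Xr.shape) * np.finfo(float).eps * max(s[0], 1.0)
    return u[:, keep]


def _orth_basis(blocks: list[np.ndarray], n: int) -> np.ndarray:
    Q = np.full((n, 1), 1.0 / math.sqrt(n))
    for X in blocks:
        inc = _orth_increment(X, Q)
        if inc.shape[1]:
            Q = np.hstack([Q, inc])
    return Q


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d.astype(float) ** 2
    n = len(a)
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def permanova(res: ResemblanceMatrix,
              terms: list[tuple[str, np.ndarray]] | None = None,
              denominators: dict[str, str] | None = None,
              n_perm: int = DEFAULT_N_PERM,
              seed: int = 0,
              max_exact: int = MAX_EXACT_PERMUTATIONS) -> pd.DataFrame:
    """Distance-based permutational ANOVA with sequential SS.

    Parameters
    ----------
    res : ResemblanceMatrix
    terms : optional ordered list of (name, design-matrix) pairs; defaults
        to the study's covariates-first nested design built from ``res.meta``.
    denominators : term -> denominator-term map for the pseudo-F ratios;
        defaults to the expected-mean-squares rules of the mixed nested
        design, with ``"Residual"`` for anything unlisted.
    n_perm : number of random permutations (ignored when the full
        permutation space has at most ``max_exact`` elements, in which case
        every permutation is enumerated and the p-value is exact).
    seed : permutation stream seed.

    Returns a table with one row per term plus Residual and Total rows:
    columns Source, df, SS, MS, pseudo-F, p, n_perm_used.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be at least 99, got {n_perm}")
    if terms is None:
        terms = default_terms(res.meta)
    denominators = dict(DEFAULT_DENOMINATORS if denominators is None else denominators)

    n = res.n
    G = _gower(res.values)
    total_ss = float(np.trace(G))

    # sequential orthonormal increments per term
    Q = np.full((n, 1), 1.0 / math.sqrt(n))
    increments: dict[str, np.ndarray] = {}
    names: list[str] = []
    for name, X in terms:
        inc = _orth_increment(np.asarray(X, dtype=float), Q)
        if inc.shape[1] == 0:
            logger.warning("PERMANOVA term %r has zero df after earlier terms; dropped", name)
            continue
        increments[name] = inc
        names.append(name)
        Q = np.hstack([Q, inc])

    df = {name: increments[name].shape[1] for name in names}
    # a trailing term that saturates the design (e.g. one survey per
    # site-month cell) is confounded with the residual: drop it
    while names and n - 1 - sum(df.values()) <= 0:
        dropped = names.pop()
        logger.warning("PERMANOVA term %r saturates the design (no residual df); dropped",
                       dropped)
        del increments[dropped], df[dropped]
    if not names:
        raise ValueError("no testable terms: design saturated")
    ss = {name: float(np.sum(increments[name] * (G @ increments[name]))) for name in names}
    df_res = n - 1 - sum(df.values())
    ss_res = total_ss - sum(ss.values())
    ms = {name: ss[name] / df[name] for name in names}
    ms["Residual"] = ss_res / df_res

    def _denom(name: str) -> str:
        d = denominators.get(name, "Residual")
        if d != "Residual" and d not in names:
            logger.warning("denominator %r for term %r unavailable; using Residual", d, name)
            d = "Residual"
        return d

    f_obs = {name: ms[name] / ms[_denom(name)] for name in names}

    # eigen-coordinates of G (signed, handles semi-metric dissimilarities)
    w, V = np.linalg.eigh(G)
    keep = np.abs(w) > 1e-10 * max(1.0, np.abs(w).max())
    w, V = w[keep], V[:, keep]
    signs = np.sign(w)
    W = V * np.sqrt(np.abs(w))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E2]))
    raw = {nm: np.asarray(X, dtype=float) for nm, X in terms if nm in names}

    def _contains(container: str, term: str) -> bool:
        """True when span(intercept + container) includes span(term)."""
        Qc = _orth_basis([raw[container]], n)
        Xk = raw[term]
        resid = Xk - Qc @ (Qc.T @ Xk)
        return float(np.abs(resid).max()) < 1e-8 * max(1.0, float(np.abs(Xk).max()))

    def _block_labels(den: str) -> np.ndarray | None:
        """Block labels when the denominator term is a categorical factor."""
        X = raw[den]
        if X.shape[1] < 2 or not np.isin(X, (0.0, 1.0)).all() \
                or not np.allclose(X.sum(axis=1), 1.0):
            return None
        return X.argmax(axis=1)

    # stacked basis: one BLAS product per permutation
    Qall = np.hstack([increments[name] for name in names])
    row_of: dict[str, slice] = {}
    start = 0
    for name in names:
        row_of[name] = slice(start, start + df[name])
        start += df[name]

    pvals: dict[str, float] = {}
    nperm_used: dict[str, int] = {}
    for k, name in enumerate(names):
        den = _denom(name)
        # reduced model: every term except the tested one and the terms whose
        # span contains it (a nested random factor absorbs the signal of the
        # factor it is nested in, so it must leave the reduced model too)
        other = [raw[nm] for nm in names
                 if nm != name and not _contains(nm, name)]
        Qr = _orth_basis(other, n)
        FW = Qr @ (Qr.T @ W)
        EW = W - FW

        # exchangeable units: levels of the denominator term (whole-block
        # permutation, restricted to equal-size blocks), or samples when the
        # denominator is the residual
        blocks = None
        if den != "Residual":
            labels = _block_labels(den)
            if labels is not None:
                by_size: dict[int, list[np.ndarray]] = {}
                for lev in np.unique(labels):
                    rows = np.flatnonzero(labels == lev)
                    by_size.setdefault(len(rows), []).append(rows)
                blocks = list(by_size.values())

        def draw_perm() -> np.ndarray:
            if blocks is None:
                return rng.permutation(n)
            idx = np.arange(n)
            for group in blocks:
                order = rng.permutation(len(group))
                for b, bp in zip(group, (group[o] for o in order)):
                    idx[b] = bp
            return idx

        def stat(idx) -> float:
            Wp = FW + EW[idx]
            colnorm = (Qall.T @ Wp) ** 2
            ss_all = {nm: float(colnorm[row_of[nm]].sum(axis=0) @ signs) for nm in names}
            tot = float((Wp * Wp).sum(axis=0) @ signs)
            res_p = tot - sum(ss_all.values())
            ms_num = ss_all[name] / df[name]
            ms_den = (res_p / df_res) if den == "Residual" else ss_all[den] / df[den]
            return ms_num / ms_den if ms_den > 0 else np.inf

        tol = 1e-9 * max(1.0, abs(f_obs[name]))
        exhaustive = blocks is None and math.factorial(n) <= max_exact
        if exhaustive:
            perms = (np.asarray(p) for p in itertools.permutations(range(n)))
            count = sum(stat(idx) >= f_obs[name] - tol for idx in perms)
            pvals[name] = count / math.factorial(n)
            nperm_used[name] = math.factorial(n)
        else:
            count = 0
            for _ in range(n_perm):
                if stat(draw_perm()) >= f_obs[name] - tol:
                    count += 1
            pvals[name] = (count + 1) / (n_perm + 1)
            nperm_used[name] = n_perm

    rows = [{"Source": name, "df": df[name], "SS": ss[name], "MS": ms[name],
             "pseudo-F": f_obs[name], "p": pvals[name],
             "denominator": _denom(name), "n_perm_used": nperm_used[name]}
            for name in names]
    rows.append({"Source": "Residual", "df": df_res, "SS": ss_res,
                 "MS": ms["Residual"], "pseudo-F": np.nan, "p": np.nan,
                 "denominator": "", "n_perm_used": 0})
    rows.append({"Source": "Total", "df": n - 1, "SS": total_ss, "MS": np.nan,
                 "pseudo-F": np.nan, "p": np.nan, "denominator": "",
                 "n_perm_used": 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise year-bin comparisons
# ---------------------------------------------------------------------------

def pairwise_year_tests(res: ResemblanceMatrix,
                        n_perm: int = DEFAULT_N_PERM,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-hoc pairwise year-bin comparisons of community structure.

    For each bin pair, a one-way two-level PERMANOVA on the subset gives
    ``t = sqrt(pseudo-F)`` with a permutation p; mean within-bin and
    between-bin dissimilarities are recomputed directly from the matrix
    entries.  Returns ``(pair_table, square_table)`` where the square table
    has within-bin means on the diagonal and between-bin means below it.
    """
    labels = res.meta["year_bin"].astype(str)
    bins = year_bin_order(labels.unique())
    square = mean_dissimilarities(res, labels)
    rows = []
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            ia = np.flatnonzero((labels == a).to_numpy())
            ib = np.flatnonzero((labels == b).to_numpy())
            if len(ia) < 2 or len(ib) < 2:
                logger.warning("pairwise %s vs %s skipped: a bin has < 2 samples", a, b)
                continue
            sel = np.concatenate([ia, ib])
            sub = ResemblanceMatrix(values=res.values[np.ix_(sel, sel)],
                                    ids=[res.ids[j] for j in sel],
                                    meta=res.meta.iloc[sel])
            groups = _dummies([a] * len(ia) + [b] * len(ib))
            tab = permanova(sub, terms=[("Group", groups)],
                            denominators={"Group": "Residual"},
                            n_perm=n_perm, seed=seed)
            f_row = tab.loc[tab["Source"] == "Group"].iloc[0]
            rows.append({
                "bin_a": a, "bin_b": b,
                "t": float(np.sqrt(max(f_row["pseudo-F"], 0.0))),
                "p": float(f_row["p"]),
                "mean_within_a": square.loc[a, a],
                "mean_within_b": square.loc[b, b],
                "mean_between": square.loc[a, b],
                "n_perm_used": int(f_row["n_perm_used"]),
            })
    return pd.DataFrame(rows), square
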