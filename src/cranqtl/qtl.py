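"""Haley-Knott QTL scans for a four-way outbred cross.

Genotype-class probabilities (AC/AD/BC/BD) are computed at markers and at
pseudomarkers on a cM grid by conditioning each parental gamete on its
nearest informative flanking markers under a Haldane Markov chain (the two
gametes are independent, so class probabilities are products of gamete
probabilities). A single-QTL scan regresses genotype BLUPs on the expected
maternal, paternal and interaction contrasts at each position; the LOD is
``(n/2)·log10(RSS0/RSS1)``. Genome-wide significance comes from permuting
the BLUP vector across genotypes and recording the maximum LOD per
permutation. Support intervals are 1.5-LOD drops; effect sizes are sums of
fitted class means following the maternal (AC+AD)-(BC+BD), paternal
(AC+BC)-(AD+BD), and interaction (AC+BD)-(AD+BC) contrasts; marker R² is
``1 - 10^(-2·LOD/n)``. A simplified stepwise search adds additive QTL
forward and prunes backward against a penalized LOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranqtl.simulate import haldane_r, validate_map

CLASS_ORDER = ("AC", "AD", "BC", "BD")


@dataclass
class GenotypeProbabilities:
    """Class probabilities on a position grid: ``probs[progeny, position, class]``."""

    grid: pd.DataFrame            # columns: linkage_group, position, is_marker, marker_id
    probs: np.ndarray             # (n_progeny, n_positions, 4), rows sum to 1
    progeny: list

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def contrasts(self) -> np.ndarray:
        """Expected maternal/paternal/interaction contrast values, (n, pos, 3)."""
        p = self.probs
        xm = p[..., 0] + p[..., 1] - p[..., 2] - p[..., 3]
        xp = p[..., 0] - p[..., 1] + p[..., 2] - p[..., 3]
        xi = p[..., 0] - p[..., 1] - p[..., 2] + p[..., 3]
        return np.stack([xm, xp, xi], axis=-1)


@dataclass(frozen=True)
class PermutationThreshold:
    n_perm: int
    percentile: float
    threshold: float
    seed: int
    max_lods: np.ndarray = field(repr=False, default=None)


@dataclass
class QtlHit:
    """One mapped QTL in the shared cross-study table schema."""

    trait: str
    population: str
    study: str
    model: str
    method: str
    linkage_group: int
    position: float
    lod: float
    marker_r2: float
    lo: float
    hi: float
    effect_maternal: float
    effect_paternal: float
    effect_interaction: float


def _gamete_probs(states: np.ndarray, marker_pos: np.ndarray,
                  grid_pos: np.ndarray) -> np.ndarray:
    """P(first parental allele) at grid positions given observed gamete states.

    ``states``: (n_progeny, n_markers) in {0, 1}, NaN-free ints (missing = -1).
    Conditioning uses the nearest informative flank on each side under the
    Haldane chain; a single flank (chromosome ends or one-sided missingness)
    falls back to the two-point probability from that flank alone.
    """
    n, m = states.shape
    out = np.full((n, len(grid_pos)), 0.5)
    informative = states >= 0
    for j, pos in enumerate(grid_pos):
        left = np.where(marker_pos <= pos)[0]
        right = np.where(marker_pos >= pos)[0]
        # exact marker with observed call: point mass
        p = np.full(n, 0.5)
        for i in range(n):
            li = next((k for k in left[::-1] if informative[i, k]), None)
            ri = next((k for k in right if informative[i, k]), None)
            if li is not None and marker_pos[li] == pos:
                p[i] = 1.0 if states[i, li] == 0 else 0.0
                continue
            if ri is not None and marker_pos[ri] == pos:
                p[i] = 1.0 if states[i, ri] == 0 else 0.0
                continue
            if li is None and ri is None:
                p[i] = 0.5
                continue
            if li is not None and ri is not None:
                rl = haldane_r(pos - marker_pos[li])
                rr = haldane_r(marker_pos[ri] - pos)
                tl = np.array([1 - rl, rl])    # P(state at pos | left state)
                tr = np.array([1 - rr, rr])
                sl, sr = states[i, li], states[i, ri]
                # P(g=0 | sl, sr) proportional to t(sl->0) t(0->sr)
                w0 = tl[sl != 0] * tr[sr != 0]
                w1 = tl[sl != 1] * tr[sr != 1]
                p[i] = w0 / (w0 + w1)
            elif li is not None:
                r = haldane_r(pos - marker_pos[li])
                p[i] = (1 - r) if states[i, li] == 0 else r
            else:
                r = haldane_r(marker_pos[ri] - pos)
                p[i] = (1 - r) if states[i, ri] == 0 else r
        out[:, j] = p
    return out


def _gamete_probs_complete(states: np.ndarray, marker_pos: np.ndarray,
                           grid_pos: np.ndarray) -> np.ndarray:
    """Vectorized flank conditioning for complete (no-missing) data."""
    n, m = states.shape
    out = np.empty((n, len(grid_pos)))
    li = np.searchsorted(marker_pos, grid_pos, side="right") - 1
    ri = np.searchsorted(marker_pos, grid_pos, side="left")
    for j, pos in enumerate(grid_pos):
        l, r = li[j], ri[j]
        if r < m and marker_pos[r] == pos:
            out[:, j] = (states[:, r] == 0).astype(float)
            continue
        if l >= 0 and r < m:
            rl = haldane_r(pos - marker_pos[l])
            rr = haldane_r(marker_pos[r] - pos)
            sl, sr = states[:, l], states[:, r]
            w0 = np.where(sl == 0, 1 - rl, rl) * np.where(sr == 0, 1 - rr, rr)
            w1 = np.where(sl == 1, 1 - rl, rl) * np.where(sr == 1, 1 - rr, rr)
            out[:, j] = w0 / (w0 + w1)
        elif l >= 0:
            rl = haldane_r(pos - marker_pos[l])
            out[:, j] = np.where(states[:, l] == 0, 1 - rl, rl)
        else:
            rr = haldane_r(marker_pos[r] - pos)
            out[:, j] = np.where(states[:, r] == 0, 1 - rr, rr)
    return out


def calc_genoprob(geno: pd.DataFrame, lmap: pd.DataFrame,
                  step: float = 1.0) -> GenotypeProbabilities:
    """Genotype-class probabilities at markers plus pseudomarkers every ``step`` cM."""
    if step <= 0:
        raise ValueError("step must be positive")
    lmap = validate_map(lmap)
    grid_rows, prob_blocks = [], []
    for lg, grp in lmap.groupby("linkage_group", sort=True):
        mpos = grp["position"].to_numpy()
        pseudo = np.arange(0.0, mpos[-1] + 1e-9, step)
        gpos = np.unique(np.concatenate([mpos, pseudo]))
        gpos = gpos[(gpos >= mpos[0]) & (gpos <= mpos[-1])]
        marker_at = {p: mid for p, mid in zip(mpos, grp["marker_id"])}
        for p in gpos:
            grid_rows.append((lg, float(p), p in marker_at, marker_at.get(p, "")))

        calls = geno[grp["marker_id"]].to_numpy().astype(str)
        mat = np.where(np.char.startswith(calls, "A"), 0,
                       np.where(np.char.startswith(calls, "B"), 1, -1))
        pat = np.where(np.char.endswith(calls, "C"), 0,
                       np.where(np.char.endswith(calls, "D"), 1, -1))
        fn = (_gamete_probs_complete if (mat >= 0).all() and (pat >= 0).all()
              else _gamete_probs)
        pA = fn(mat, mpos, gpos)
        pC = fn(pat, mpos, gpos)
        block = np.stack([pA * pC, pA * (1 - pC),
                          (1 - pA) * pC, (1 - pA) * (1 - pC)], axis=-1)
        prob_blocks.append(block)
    grid = pd.DataFrame(grid_rows,
                        columns=["linkage_group", "position", "is_marker", "marker_id"])
    return GenotypeProbabilities(grid, np.concatenate(prob_blocks, axis=1),
                                 list(geno.index))


def _position_bases(probs: GenotypeProbabilities) -> list[np.ndarray]:
    """Orthonormal bases of [1, contrasts] per position, for fast RSS computation."""
    n = len(probs.progeny)
    ones = np.ones((n, 1))
    contrasts = probs.contrasts()
    bases = []
    for j in range(probs.n_positions):
        Xj = np.hstack([ones, contrasts[:, j, :]])
        Q, R = np.linalg.qr(Xj)
        keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R[0, 0]))
        bases.append(Q[:, keep])
    return bases


def _lod_matrix(bases: list[np.ndarray], Y: np.ndarray) -> np.ndarray:
    """LOD at every position (rows) for every phenotype column of Y."""
    n = Y.shape[0]
    yty = (Y ** 2).sum(axis=0)
    rss0 = yty - n * Y.mean(axis=0) ** 2
    lods = np.empty((len(bases), Y.shape[1]))
    for j, Q in enumerate(bases):
        proj = Q.T @ Y
        rss1 = np.clip(yty - (proj ** 2).sum(axis=0), 1e-300, None)
        lods[j] = (n / 2.0) * np.log10(np.clip(rss0, 1e-300, None) / rss1)
    return np.clip(lods, 0.0, None)


def scanone_hk(probs: GenotypeProbabilities, blups: np.ndarray) -> pd.DataFrame:
    """Single-QTL Haley-Knott genome scan; returns the LOD curve as a DataFrame."""
    y = np.asarray(blups, dtype=float).ravel()
    if len(y) != len(probs.progeny):
        raise ValueError("phenotype length does not match progeny count")
    if len(y) < 8:
        raise ValueError("need >= 8 genotypes")
    bases = _position_bases(probs)
    lod = _lod_matrix(bases, y[:, None])[:, 0]
    curve = probs.grid.copy()
    curve["lod"] = lod
    return curve


def permutation_threshold(probs: GenotypeProbabilities, blups: np.ndarray,
                          n_perm: int = 1000, percentile: float = 80.0,
                          seed: int = 0) -> PermutationThreshold:
    """Genome-wide LOD threshold from phenotype permutations.

    The BLUP vector is permuted across genotypes ``n_perm`` times; the
    genome-wide maximum LOD of each permutation forms the null distribution
    whose stated percentile is the threshold.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    y = np.asarray(blups, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    Y = np.empty((len(y), n_perm))
    for k in range(n_perm):
        Y[:, k] = rng.permutation(y)
    bases = _position_bases(probs)
    max_lods = _lod_matrix(bases, Y).max(axis=0)
    thr = float(np.percentile(max_lods, percentile))
    return PermutationThreshold(n_perm, percentile, thr, seed, max_lods)


def lod_interval(curve: pd.DataFrame, drop: float = 1.5,
                 peak_index: int | None = None) -> tuple[float, float, int]:
    """1.5-LOD support interval on the peak's linkage group.

    Returns ``(lo, hi, peak_index)`` where lo/hi are the outermost grid
    positions on that linkage group with LOD >= peak - drop. Ties for the
    peak go to the leftmost position.
    """
    if peak_index is None:
        peak_index = int(curve["lod"].idxmax())   # idxmax returns first max
    peak = curve.loc[peak_index]
    lg = curve[curve["linkage_group"] == peak["linkage_group"]]
    inside = lg[lg["lod"] >= peak["lod"] - drop]
    return float(inside["position"].min()), float(inside["position"].max()), peak_index


def effects_and_r2(probs: GenotypeProbabilities, position_index: int,
                   blups: np.ndarray, lod: float
                   ) -> tuple[float, float, float, float]:
    """Parental-contrast effect sizes and marker R² at a fitted peak.

    Class means are estimated by regressing the BLUPs on the four expected
    class probabilities (no intercept); effects are the contrast sums of
    those means. ``marker_r2 = 1 - 10^(-2·LOD/n)``. An empty class at a
    complete-data position leaves the effects undefined (NaN).
    """
    y = np.asarray(blups, dtype=float).ravel()
    P4 = probs.probs[:, position_index, :]
    n = len(y)
    if np.any(P4.sum(axis=0) < 1e-9):
        return float("nan"), float("nan"), float("nan"), _marker_r2(lod, n)
    m, *_ = np.linalg.lstsq(P4, y, rcond=None)
    av_b = (m[0] + m[1]) - (m[2] + m[3])
    cv_d = (m[0] + m[2]) - (m[1] + m[3])
    inter = (m[0] + m[3]) - (m[1] + m[2])
    return float(av_b), float(cv_d), float(inter), _marker_r2(lod, n)


def _marker_r2(lod: float, n: int) -> float:
    return float(1.0 - 10.0 ** (-2.0 * lod / n))


def scan_to_hit(probs: GenotypeProbabilities, blups: np.ndarray,
                curve: pd.DataFrame, drop: float = 1.5, *, trait: str = "",
                population: str = "", study: str = "", model: str = "",
                method: str = "scanone") -> QtlHit:
    """Package the peak of a scan into a QtlHit record."""
    lo, hi, pk = lod_interval(curve, drop)
    peak = curve.loc[pk]
    av, cv, it, r2 = effects_and_r2(probs, pk, blups, float(peak["lod"]))
    return QtlHit(trait, population, study, model, method,
                  int(peak["linkage_group"]), float(peak["position"]),
                  float(peak["lod"]), r2, lo, hi, av, cv, it)


# ---------------------------------------------------------------------------
# simplified stepwise search (additive terms, single main penalty)

def _model_rss(contrasts: np.ndarray, positions: list[int],
               y: np.ndarray) -> float:
    n = len(y)
    X = np.ones((n, 1 + 3 * len(positions)))
    for k, j in enumerate(positions):
        X[:, 1 + 3 * k:4 + 3 * k] = contrasts[:, j, :]
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def stepwise_scan(probs: GenotypeProbabilities, blups: np.ndarray,
                  main_penalty: float, max_qtl: int = 6, drop: float = 1.5,
                  *, trait: str = "", population: str = "", study: str = "",
                  model: str = "") -> list[QtlHit]:
    """Forward/backward search over additive QTL maximizing a penalized LOD.

    ``pLOD(model) = LOD(model) - penalty · #QTL`` with the penalty taken
    from the 95th-percentile permutation threshold. Forward steps add the
    position that best raises pLOD; backward steps drop members while that
    improves it. Per-QTL support intervals and effects come from profile
    curves with the other QTL fixed.
    """
    y = np.asarray(blups, dtype=float).ravel()
    n = len(y)
    if not np.isfinite(main_penalty):
        return []
    contrasts = probs.contrasts()
    rss_null = float(((y - y.mean()) ** 2).sum())

    def plod(positions: list[int]) -> float:
        if not positions:
            return 0.0
        rss = max(_model_rss(contrasts, positions, y), 1e-300)
        lod = (n / 2.0) * np.log10(rss_null / rss)
        return lod - main_penalty * len(positions)

    current: list[int] = []
    best_score = 0.0
    improved = True
    while improved and len(current) < max_qtl:
        improved = False
        # forward: best single addition
        cand_scores = np.full(probs.n_positions, -np.inf)
        for j in range(probs.n_positions):
            if j in current:
                continue
            cand_scores[j] = plod(current + [j])
        j_best = int(np.argmax(cand_scores))
        if cand_scores[j_best] > best_score + 1e-9:
            current.append(j_best)
            best_score = cand_scores[j_best]
            improved = True
            # backward: prune while it helps
            pruning = True
            while pruning and len(current) > 1:
                pruning = False
                for j in list(current):
                    rest = [k for k in current if k != j]
                    if plod(rest) > best_score + 1e-9:
                        current = rest
                        best_score = plod(rest)
                        pruning = True
                        break

    hits = []
    grid = probs.grid
    for j in sorted(current):
        others = [k for k in current if k != j]
        lg = grid.loc[j, "linkage_group"]
        lg_idx = grid.index[grid["linkage_group"] == lg].to_numpy()
        prof = np.empty(len(lg_idx))
        base_rss = _model_rss(contrasts, others, y) if others else rss_null
        for t, jj in enumerate(lg_idx):
            rss = max(_model_rss(contrasts, others + [int(jj)], y), 1e-300)
            prof[t] = (n / 2.0) * np.log10(base_rss / rss)
        pk_local = int(np.argmax(prof))
        peak_lod = prof[pk_local]
        inside = lg_idx[prof >= peak_lod - drop]
        lo = float(grid.loc[inside, "position"].min())
        hi = float(grid.loc[inside, "position"].max())
        pk_global = int(lg_idx[pk_local])
        av, cv, it, r2 = effects_and_r2(probs, pk_global, y, float(peak_lod))
        hits.append(QtlHit(trait, population, study, model, "stepwiseqtl",
                           int(lg), float(grid.loc[pk_global, "position"]),
                           float(peak_lod), r2, lo, hi, av, cv, it))
    return hits


def hits_to_frame(hits: list[QtlHit]) -> pd.DataFrame:
    """QtlHit records as the shared cross-study QTL table."""
    cols = ["trait", "population", "study", "model", "method", "linkage_group",
            "position", "lod", "marker_r2", "lo", "hi",
            "effect_maternal", "effect_paternal", "effect_interaction"]
    return pd.DataFrame([[getattr(h, c) for c in cols] for h in hits], columns=cols)
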