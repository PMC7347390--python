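"""Unsupervised behavioral-state discovery from posture time series.

The stack has four levels.  (1) A *posture compendium*: hierarchical
clustering of observed 14-angle posture vectors yields a library of
reference postures, sized by a variance-explained stopping rule; every
frame is then described by its nearest reference posture.  (2) *Posture
groups*: k-means on the rows of the posture-to-posture transition matrix
(self-transitions excluded) reveals blocks of postures animals shuttle
among; the intra/inter transition-probability ratio selects the group
count.  (3) *Coarsening*: each 3-s interval is summarized by its
posture-group composition vector and mapped, via silhouette-selected
k-means, to a single coarsened-group symbol.  (4) A discrete-emission HMM
over those symbols, sized by BIC and decoded with Viterbi, segments the
recording into long-lasting behavioral states (one roaming state plus
dwelling sub-modes).

A final model comparison asks whether the posture-HMM describes dwelling
better than memoryless alternatives, using the mean first-passage time
between every pair of postures as the summary statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import _splines
from .record import BehaviorRecord

DEFAULT_N_GROUPS = 8
EMISSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass
class PostureCompendium:
    prototypes: np.ndarray  # (K, 14), mean-centered
    variance_explained: float
    selection_curve: np.ndarray  # variance explained at sizes 1..max_K

    @property
    def size(self) -> int:
        return self.prototypes.shape[0]


@dataclass
class PostureGroups:
    assignment: np.ndarray  # group id (0..G-1) per reference posture
    intra_inter_ratio: float

    @property
    def n_groups(self) -> int:
        return int(self.assignment.max()) + 1


@dataclass
class TransitionMatrix:
    probs: np.ndarray  # (K, K) row-stochastic over off-diagonal entries
    counts: np.ndarray
    defined_rows: np.ndarray  # False where a posture had no outgoing transition


@dataclass
class CoarseSequence:
    symbols: np.ndarray  # coarsened group per 3-s bin; -1 = missing
    fractions: np.ndarray  # (n_bins, n_groups) composition vectors
    bin_s: float = 3.0

    @property
    def n_bins(self) -> int:
        return self.symbols.size


@dataclass
class PostureHMM:
    transition: np.ndarray
    emission: np.ndarray
    log_likelihood: float
    bic: float
    n_obs: int

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[1]


@dataclass
class StatePath:
    states: np.ndarray  # hidden state per bin; -1 where the symbol was missing
    labels: dict[int, str]  # semantic label per state (roam / dwell sub-mode)


# ---------------------------------------------------------------------------
# alignment


def ventral_align(records: list[BehaviorRecord]) -> list[BehaviorRecord]:
    """Negate body angles of animals traveling on their left side so all
    animals share one dorsal-ventral axis.  Records with unknown ventral
    side are excluded with a warning.  Applying the alignment twice is the
    identity."""
    out = []
    for rec in records:
        if rec.ventral_side == "unknown":
            warnings.warn("excluding record with unknown ventral side")
            continue
        if rec.ventral_side == "left":
            rec = replace(rec, posture=-rec.posture)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# compendium


def _mean_center(coeff_rows: np.ndarray) -> np.ndarray:
    """Shift spline coefficients so the reconstructed angle profile has mean 0."""
    B = _splines.design_matrix(coeff_rows.shape[1], 1000)
    shift = (coeff_rows @ B.T).mean(axis=1, keepdims=True)
    return coeff_rows - shift


def build_compendium(
    postures: np.ndarray,
    max_K: int = 200,
    variance_floor: float = 0.75,
    marginal_gain: float = 0.01,
    cluster_sample: int = 10_000,
    refine_iters: int = 2,
    seed: int = 0,
) -> PostureCompendium:
    """Reference-posture library by Ward hierarchical clustering.

    The dendrogram is cut at every depth 1..max_K; prototypes are cluster
    means and variance explained is 1 - SS_within/SS_total.  The selected
    size is the smallest K explaining at least ``variance_floor`` of the
    postural variance while the next posture adds less than
    ``marginal_gain``.  If no K qualifies, max_K is returned with a
    warning.

    Ward's objective makes the selection curve cheap: each merge of height
    h raises the within-cluster sum of squares by h^2/2, so the whole
    curve follows from the linkage heights.  For tractability the tree is
    built on a random subsample of ``cluster_sample`` vectors (the
    selection statistics are computed there); the reported
    ``variance_explained`` is then re-evaluated on the full input under
    nearest-prototype assignment.
    """
    postures = np.asarray(postures, dtype=float)
    N = postures.shape[0]
    if N < max_K:
        raise ValueError(f"need at least max_K={max_K} posture vectors, got {N}")
    rng = np.random.default_rng(seed)
    if N > cluster_sample:
        sample = postures[rng.choice(N, cluster_sample, replace=False)]
    else:
        sample = postures
    n = sample.shape[0]
    Z = linkage(sample, method="ward")
    ss_tot = float(((sample - sample.mean(axis=0)) ** 2).sum())
    # SS_within after the first m merges = sum of h_i^2 / 2
    merge_ss = np.concatenate([[0.0], np.cumsum(Z[:, 2] ** 2) / 2.0])
    curve = np.empty(max_K)
    for K in range(1, max_K + 1):
        curve[K - 1] = 1.0 - merge_ss[min(n - K, n - 1)] / ss_tot

    selected = None
    for K in range(1, max_K):
        if curve[K - 1] >= variance_floor and (curve[K] - curve[K - 1]) < marginal_gain:
            selected = K
            break
    if selected is None:
        warnings.warn(
            f"stopping rule unmet within max_K={max_K}; returning max_K prototypes"
        )
        selected = max_K

    labels = fcluster(Z, t=selected, criterion="maxclust")
    prototypes = np.stack(
        [sample[labels == c].mean(axis=0) for c in range(1, selected + 1)]
    )
    # refine on the full input: prototypes are the means of the postures
    # assigned to them, so recompute the means under full-data assignment
    for _ in range(refine_iters):
        ids = _nearest_prototype_ids(postures, prototypes)
        for c in range(selected):
            sel = ids == c
            if sel.any():
                prototypes[c] = postures[sel].mean(axis=0)
    prototypes = _mean_center(prototypes)

    d2 = _nearest_prototype_sq_dist(postures, prototypes)
    ss_tot_full = float(((postures - postures.mean(axis=0)) ** 2).sum())
    ve_full = 1.0 - float(d2.sum()) / ss_tot_full
    return PostureCompendium(
        prototypes=prototypes, variance_explained=ve_full, selection_curve=curve
    )


def _nearest_prototype_ids(
    postures: np.ndarray, prototypes: np.ndarray, chunk: int = 20_000
) -> np.ndarray:
    out = np.empty(postures.shape[0], dtype=int)
    for i in range(0, postures.shape[0], chunk):
        d = cdist(postures[i : i + chunk], prototypes, "sqeuclidean")
        out[i : i + chunk] = d.argmin(axis=1)
    return out


def _nearest_prototype_sq_dist(
    postures: np.ndarray, prototypes: np.ndarray, chunk: int = 20_000
) -> np.ndarray:
    out = np.empty(postures.shape[0])
    for i in range(0, postures.shape[0], chunk):
        d = cdist(postures[i : i + chunk], prototypes, "sqeuclidean")
        out[i : i + chunk] = d.min(axis=1)
    return out


def assign_postures(
    postures: np.ndarray,
    compendium: PostureCompendium,
    valid: np.ndarray | None = None,
    chunk: int = 20_000,
) -> np.ndarray:
    """Nearest reference posture (Euclidean on 14-vectors) per frame.

    Ties resolve to the lowest prototype index; invalid frames get -1.
    """
    postures = np.asarray(postures, dtype=float)
    ids = np.full(postures.shape[0], -1, dtype=int)
    idx = (
        np.flatnonzero(np.asarray(valid, bool))
        if valid is not None
        else np.arange(postures.shape[0])
    )
    for i in range(0, idx.size, chunk):
        sel = idx[i : i + chunk]
        d = cdist(postures[sel], compendium.prototypes, "sqeuclidean")
        ids[sel] = d.argmin(axis=1)
    return ids


# ---------------------------------------------------------------------------
# transitions and posture groups


def build_transition_matrix(posture_ids: np.ndarray, n_postures: int | None = None
                            ) -> TransitionMatrix:
    """Posture-to-posture transition probabilities, ignoring self-transitions.

    ``posture_ids`` uses -1 for invalid frames; transitions are counted
    only between consecutive valid frames.  Rows without any outgoing
    transition are flagged and left as zeros.
    """
    ids = np.asarray(posture_ids, dtype=int)
    if ids.size < 2:
        raise ValueError("need at least two frames")
    K = int(n_postures if n_postures is not None else ids.max() + 1)
    a, b = ids[:-1], ids[1:]
    ok = (a >= 0) & (b >= 0) & (a != b)
    counts = np.zeros((K, K))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    rowsum = counts.sum(axis=1)
    defined = rowsum > 0
    probs = np.zeros_like(counts)
    probs[defined] = counts[defined] / rowsum[defined, None]
    return TransitionMatrix(probs=probs, counts=counts, defined_rows=defined)


def block_ratio(T: np.ndarray, labels: np.ndarray) -> float:
    """Mean intra-group / mean inter-group off-diagonal transition probability."""
    K = T.shape[0]
    off = ~np.eye(K, dtype=bool)
    same = labels[:, None] == labels[None, :]
    intra = T[off & same]
    inter = T[off & ~same]
    if intra.size == 0 or inter.size == 0 or inter.mean() == 0:
        return np.nan
    return float(intra.mean() / inter.mean())


def cluster_posture_groups(
    T: TransitionMatrix,
    k_range: range = range(2, 11),
    n_restarts: int = 500,
    seed: int = 0,
) -> tuple[PostureGroups, int]:
    """Posture groups by repeated k-means on the transition-matrix rows.

    For each candidate group count the best of ``n_restarts`` k-means
    clusterings (by the intra/inter block ratio) is kept; the count with
    the highest ratio wins.  The criterion is invariant to simultaneous
    row/column permutations of the matrix.
    """
    rows = T.probs
    rng = np.random.default_rng(seed)
    best_by_k: dict[int, tuple[float, np.ndarray]] = {}
    for k in k_range:
        best = (-np.inf, None)
        for _ in range(n_restarts):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate restarts are discarded
                km = KMeans(
                    n_clusters=k, n_init=1, random_state=int(rng.integers(2**31))
                ).fit(rows)
            labels = km.labels_
            if np.unique(labels).size < k:
                continue  # degenerate restart
            ratio = block_ratio(rows, labels)
            if np.isfinite(ratio) and ratio > best[0]:
                best = (ratio, labels)
        if best[1] is not None:
            best_by_k[k] = best
    if not best_by_k:
        raise ValueError("no valid clustering found in any restart")
    k_opt = max(best_by_k, key=lambda k: best_by_k[k][0])
    ratio, labels = best_by_k[k_opt]
    return PostureGroups(assignment=labels, intra_inter_ratio=ratio), k_opt


# ---------------------------------------------------------------------------
# coarsening


def coarsen_intervals(
    group_ids: np.ndarray,
    frame_rate: float,
    n_groups: int = DEFAULT_N_GROUPS,
    bin_s: float = 3.0,
    k_range: range = range(2, 13),
    n_restarts: int = 10,
    seed: int = 0,
    silhouette_sample: int = 4000,
) -> tuple[CoarseSequence, int]:
    """Summarize 3-s intervals by posture-group composition and cluster them.

    Each bin's eight-element composition vector (fraction of frames in
    each posture group; -1 entries are missing frames) is clustered by
    k-means with the cluster count chosen by mean silhouette.  Each
    cluster is then identified with its dominant posture group; when that
    mapping is one-to-one, bin symbols are the dominant-group ids, giving
    each interval a single coarsened value.  Bins with more than half
    their frames missing get the missing symbol -1.
    """
    ids = np.asarray(group_ids, dtype=int)
    frames_per_bin = int(round(bin_s * frame_rate))
    n_bins = ids.size // frames_per_bin
    if n_bins == 0:
        raise ValueError("sequence shorter than one coarsening bin")
    fractions = np.zeros((n_bins, n_groups))
    missing = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        chunk = ids[b * frames_per_bin : (b + 1) * frames_per_bin]
        good = chunk[chunk >= 0]
        if good.size < frames_per_bin / 2:
            missing[b] = True
            continue
        fractions[b] = np.bincount(good, minlength=n_groups) / good.size

    X = fractions[~missing]
    if X.shape[0] < max(k_range) + 1:
        raise ValueError("too few valid bins to cluster")
    rng = np.random.default_rng(seed)
    best = (-np.inf, None, None)
    for k in k_range:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point restarts at large k
            km = KMeans(n_clusters=k, n_init=n_restarts,
                        random_state=int(rng.integers(2**31))).fit(X)
        sample_kw = {}
        if X.shape[0] > silhouette_sample:
            sample_kw = dict(
                sample_size=silhouette_sample, random_state=int(rng.integers(2**31))
            )
        try:
            score = silhouette_score(X, km.labels_, **sample_kw)
        except ValueError:
            continue
        if score > best[0]:
            best = (score, k, km)
    _, k_opt, km = best
    if km is None:
        # degenerate data (e.g. a single distinct composition): one cluster
        dominant_all = int(np.argmax(X.mean(axis=0)))
        symbols = np.full(n_bins, -1, dtype=int)
        symbols[~missing] = dominant_all
        return CoarseSequence(symbols=symbols, fractions=fractions, bin_s=bin_s), 1

    labels = km.predict(X)
    dominant = np.array(
        [int(np.argmax(km.cluster_centers_[c])) for c in range(k_opt)]
    )
    symbols = np.full(n_bins, -1, dtype=int)
    if np.unique(dominant).size == k_opt:
        symbols[~missing] = dominant[labels]  # bijective: use group identity
    else:
        symbols[~missing] = labels
    return CoarseSequence(symbols=symbols, fractions=fractions, bin_s=bin_s), k_opt


# ---------------------------------------------------------------------------
# HMM training and selection


def _segments(symbols: np.ndarray) -> list[np.ndarray]:
    """Contiguous runs of non-missing symbols; missing bins split sequences."""
    idx = np.flatnonzero(symbols >= 0)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [symbols[run] for run in np.split(idx, splits)]


def _as_symbol_arrays(sequences) -> list[np.ndarray]:
    out = []
    for s in sequences:
        arr = s.symbols if isinstance(s, CoarseSequence) else np.asarray(s, int)
        out.extend(_segments(arr))
    return out


def _kmeans_emission_init(
    X: np.ndarray,
    n_states: int,
    n_symbols: int,
    rng: np.random.Generator,
    window: int = 20,
) -> np.ndarray:
    """Emission rows from k-means centers of sliding-window symbol histograms."""
    nw = max(n_states, X.size // window)
    H = np.zeros((min(nw, X.size), n_symbols))
    for w in range(H.shape[0]):
        chunk = X[w * window : (w + 1) * window]
        if chunk.size == 0:
            chunk = X[-window:]
        H[w] = np.bincount(chunk, minlength=n_symbols) / chunk.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate windows are harmless here
        km = KMeans(
            n_clusters=n_states, n_init=3, random_state=int(rng.integers(2**31))
        ).fit(H)
    e0 = km.cluster_centers_ + 0.02
    return e0 / e0.sum(axis=1, keepdims=True)


def train_hmm(
    sequences,
    n_states: int,
    n_restarts: int = 5,
    seed: int = 0,
    n_symbols: int = DEFAULT_N_GROUPS,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> PostureHMM:
    """Baum-Welch fit of a discrete-emission HMM over coarsened groups.

    Transition and emission matrices are randomly initialized per restart
    (Dirichlet rows); the initial-state distribution is fixed uniform.
    The best restart by log-likelihood is returned, with
    BIC = -2 logL + p ln(n), p = n_states(n_states-1) + n_states(n_symbols-1).
    Missing symbols split training sequences rather than being imputed.
    """
    from . import _hmm_core

    segs = _as_symbol_arrays(sequences)
    if not segs:
        raise ValueError("no non-missing symbols to train on")
    X = np.concatenate(segs)
    lengths = [len(s) for s in segs]
    n_obs = X.shape[0]
    if np.unique(X).size < n_states:
        warnings.warn(
            "fewer distinct symbols than hidden states; model may be degenerate"
        )
    rng = np.random.default_rng(seed)
    best: PostureHMM | None = None
    for r in range(max(1, n_restarts)):
        # sticky transition init: behavioral states persist for many bins,
        # and EM from a fully random transition matrix crawls toward such
        # solutions through long plateaus; seeding the diagonal avoids that
        trans0 = 0.9 * np.eye(n_states) + 0.1 * rng.dirichlet(
            np.ones(n_states), size=n_states
        )
        # emission init alternates between k-means on windowed symbol
        # compositions (a data-driven start that lands EM in the dominant
        # basin) and fully random rows (independent multi-start probes)
        if r % 2 == 0:
            emit0 = _kmeans_emission_init(X, n_states, n_symbols, rng)
        else:
            emit0 = rng.dirichlet(np.ones(n_symbols), size=n_states)
        trans, emit, logl, _ = _hmm_core.baum_welch(
            X, lengths, n_states, n_symbols, trans0, emit0,
            tol=tol, max_iter=max_iter,
        )
        if not np.isfinite(logl):
            continue
        p = n_states * (n_states - 1) + n_states * (n_symbols - 1)
        bic = -2.0 * logl + p * np.log(n_obs)
        cand = PostureHMM(
            transition=trans,
            emission=emit,
            log_likelihood=logl,
            bic=float(bic),
            n_obs=n_obs,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    if best is None:
        raise RuntimeError("all HMM restarts failed to converge")
    return best


def select_model_bic(
    sequences,
    state_range: range = range(2, 13),
    n_restarts: int = 3,
    seed: int = 0,
    n_symbols: int = DEFAULT_N_GROUPS,
) -> tuple[int, dict[int, float], dict[int, PostureHMM]]:
    """Median-BIC model selection over a range of hidden-state counts.

    Each restart is an independently initialized training run; the state
    count minimizing the median BIC wins.  Returns (best count, median-BIC
    curve, best model per count).
    """
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    models: dict[int, PostureHMM] = {}
    for n_states in state_range:
        fits = [
            train_hmm(
                sequences,
                n_states,
                n_restarts=1,
                seed=int(rng.integers(2**31)),
                n_symbols=n_symbols,
            )
            for _ in range(n_restarts)
        ]
        curve[n_states] = float(np.median([f.bic for f in fits]))
        models[n_states] = min(fits, key=lambda f: f.bic)
    best_n = min(curve, key=curve.get)
    return best_n, curve, models


def compare_models(models: list[PostureHMM]) -> np.ndarray:
    """Pairwise model dissimilarity: mean Euclidean distance between
    emission-matrix rows after optimal state matching (so the measure is
    invariant to state relabeling)."""
    sizes = {m.n_states for m in models}
    if len(sizes) != 1:
        raise ValueError("all models must have the same number of states")
    n = len(models)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cost = cdist(models[i].emission, models[j].emission)
            r, c = linear_sum_assignment(cost)
            out[i, j] = out[j, i] = float(cost[r, c].mean())
    return out


# ---------------------------------------------------------------------------
# decoding


def _viterbi_segment(
    log_trans: np.ndarray, log_emit: np.ndarray, symbols: np.ndarray
) -> np.ndarray:
    n_states = log_trans.shape[0]
    T = symbols.size
    delta = np.full((T, n_states), -np.inf)
    psi = np.zeros((T, n_states), dtype=int)
    delta[0] = -np.log(n_states) + log_emit[:, symbols[0]]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + log_trans
        psi[t] = scores.argmax(axis=0)
        delta[t] = scores.max(axis=0) + log_emit[:, symbols[t]]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta[-1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def viterbi_decode(
    model: PostureHMM,
    symbols: np.ndarray,
    velocity_per_bin: np.ndarray | None = None,
) -> StatePath:
    """Most probable state path per contiguous non-missing segment.

    Emissions are floor-smoothed (1e-8, renormalized) during decoding only,
    so symbols unseen in training cannot zero out a whole segment; a
    warning is raised when the floor is actually exercised.  States are
    labeled post hoc: the state with the highest mean velocity (when
    locomotion is supplied) is 'roam'; the rest are dwell sub-modes
    numbered by descending occupancy.
    """
    symbols = np.asarray(
        symbols.symbols if isinstance(symbols, CoarseSequence) else symbols, int
    )
    emission = model.emission
    valid_syms = symbols[symbols >= 0]
    if valid_syms.size and np.any(emission[:, np.unique(valid_syms)].max(axis=0) <= 0):
        warnings.warn("symbol with zero probability under all states; floor-smoothing")
    emission = emission + EMISSION_FLOOR
    emission = emission / emission.sum(axis=1, keepdims=True)
    log_trans = np.log(model.transition + EMISSION_FLOOR)
    log_emit = np.log(emission)

    states = np.full(symbols.size, -1, dtype=int)
    idx = np.flatnonzero(symbols >= 0)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            states[run] = _viterbi_segment(log_trans, log_emit, symbols[run])

    labels: dict[int, str] = {}
    occupancy = np.bincount(states[states >= 0], minlength=model.n_states)
    order = np.argsort(-occupancy)
    if velocity_per_bin is not None:
        v = np.asarray(velocity_per_bin, dtype=float)
        mean_v = np.full(model.n_states, -np.inf)
        for s in range(model.n_states):
            sel = states == s
            if sel.any():
                mean_v[s] = np.nanmean(v[sel])
        roam = int(np.argmax(mean_v))
        labels[roam] = "roam"
        order = [s for s in order if s != roam]
    rank = 1
    for s in order:
        labels[int(s)] = f"dwell{rank}"
        rank += 1
    return StatePath(states=states, labels=labels)


# ---------------------------------------------------------------------------
# dwelling-model comparison


def similarity_transition_matrix(prototypes: np.ndarray) -> np.ndarray:
    """Posture-similarity transitions: P(i->j) ∝ exp(-d_ij^2 / 2 sigma^2)
    with sigma the median inter-prototype distance, zero diagonal."""
    d = squareform(pdist(prototypes))
    sigma = np.median(d[np.triu_indices_from(d, k=1)])
    P = np.exp(-(d**2) / (2 * sigma**2))
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


def simulate_dwelling_models(
    model_kind: str,
    n_frames: int,
    frame_rate: float,
    transition: np.ndarray,
    duration_dists: list[np.ndarray],
    seed: int = 0,
    prototypes: np.ndarray | None = None,
    hmm: PostureHMM | None = None,
    group_of_posture: np.ndarray | None = None,
    roaming_state: int | None = None,
) -> np.ndarray:
    """Synthetic posture-id sequences under three generative hypotheses.

    'posture-hmm': coarse groups follow the HMM (roaming bins excised);
    within the active group, postures hop by the empirical within-group
    transition rates.  'empirical-transition': postures hop by the full
    empirical transition matrix, no group structure.
    'similarity-transition': hop probabilities decay with inter-prototype
    Euclidean distance.  In every case each posture is held for a dwell
    time drawn from its empirical duration distribution (seconds).
    """
    rng = np.random.default_rng(seed)
    K = transition.shape[0]

    if model_kind == "similarity-transition":
        if prototypes is None:
            raise ValueError("similarity model needs prototypes")
        P = similarity_transition_matrix(prototypes)
    elif model_kind in ("empirical-transition", "posture-hmm"):
        P = transition
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    group_seq = None
    if model_kind == "posture-hmm":
        if hmm is None or group_of_posture is None:
            raise ValueError("posture-hmm model needs hmm and group_of_posture")
        frames_per_bin = int(round(3.0 * frame_rate))
        n_bins = int(np.ceil(n_frames / frames_per_bin)) * 2 + 10
        state = rng.integers(hmm.n_states)
        states, syms = [], []
        for _ in range(n_bins):
            state = rng.choice(hmm.n_states, p=hmm.transition[state])
            states.append(state)
            syms.append(rng.choice(hmm.n_symbols, p=hmm.emission[state]))
        states, syms = np.asarray(states), np.asarray(syms)
        if roaming_state is not None:  # dwelling only: excise roaming bins
            syms = syms[states != roaming_state]
        group_seq = np.repeat(syms, frames_per_bin)

    ids = np.empty(n_frames, dtype=int)
    pos = 0
    current = -1
    while pos < n_frames:
        if model_kind == "posture-hmm":
            g = group_seq[min(pos, group_seq.size - 1)]
            members = np.flatnonzero(group_of_posture == g)
            if current < 0 or group_of_posture[current] != g:
                current = int(rng.choice(members))
            else:
                w = P[current, members].copy()
                w[members == current] = 0.0
                current = (
                    int(rng.choice(members, p=w / w.sum()))
                    if w.sum() > 0
                    else int(rng.choice(members))
                )
        else:
            if current < 0:
                current = int(rng.integers(K))
            else:
                w = P[current].copy()
                w[current] = 0.0
                current = int(rng.choice(K, p=w / w.sum()))
        dur_s = float(rng.choice(duration_dists[current]))
        n = max(1, int(round(dur_s * frame_rate)))
        ids[pos : pos + n] = current
        pos += n
    return ids


def empirical_duration_dists(
    posture_ids: np.ndarray, frame_rate: float, n_postures: int
) -> list[np.ndarray]:
    """Per-posture dwell-time distributions (seconds) from a frame-level sequence."""
    ids = np.asarray(posture_ids, int)
    change = np.flatnonzero(np.diff(ids) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [ids.size]])
    dists: list[list[float]] = [[] for _ in range(n_postures)]
    for s, e in zip(starts, ends):
        if ids[s] >= 0:
            dists[ids[s]].append((e - s) / frame_rate)
    return [
        np.asarray(d) if d else np.asarray([1.0 / frame_rate]) for d in dists
    ]


def pairwise_recurrence_metric(
    posture_ids: np.ndarray, frame_rate: float, n_postures: int | None = None
) -> np.ndarray:
    """Mean first-passage time (s) from each posture to every other.

    Entry (i, j) is the average, over frames showing posture i, of the
    time until posture j is next observed (strictly later); frames with no
    subsequent j are excluded.  The diagonal is the mean recurrence time.
    Postures never observed give missing (NaN) rows/columns.
    """
    ids = np.asarray(posture_ids, int)
    K = int(n_postures if n_postures is not None else ids.max() + 1)
    T = ids.size
    out = np.full((K, K), np.nan)
    occupied = np.bincount(ids[ids >= 0], minlength=K) > 0
    t = np.arange(T, dtype=float) / frame_rate
    for j in range(K):
        if not occupied[j]:
            continue
        idx_j = np.flatnonzero(ids == j)
        pos = np.searchsorted(idx_j, np.arange(T), side="right")
        nxt = np.full(T, np.nan)
        has_next = pos < idx_j.size
        nxt[has_next] = t[idx_j[pos[has_next]]]
        wait = nxt - t
        ok = (ids >= 0) & np.isfinite(wait)
        sums = np.bincount(ids[ok], weights=wait[ok], minlength=K)
        cnts = np.bincount(ids[ok], minlength=K)
        has = cnts > 0
        out[has, j] = sums[has] / cnts[has]
    return out


def model_error(synthetic: np.ndarray, real: np.ndarray) -> float:
    """Summed squared difference of the recurrence matrices over the pairs
    defined in both (NaNs excluded pairwise)."""
    a, b = np.asarray(synthetic, float), np.asarray(real, float)
    if a.shape != b.shape:
        raise ValueError("matrices must have matching posture sets")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no overlapping defined pairs")
    return float(((a[ok] - b[ok]) ** 2).sum())
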