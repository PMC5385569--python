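"""Parameter set of the two-level chromatin-state HMM.

The model annotates a genome at two interlocking scales. Each 200 bp bin
carries a *nucleosome-level* state k in {0..K_n-1}; each block of D_S
consecutive bins carries a *domain-level* state mu in {0..K_d-1}. The
parameter families are:

- ``emissions`` E (K_n x M): Bernoulli success probability of each chromatin
  mark given the nucleosome-level state. Emissions are independent of the
  domain-level state.
- ``nuc_trans`` t (K_d x K_n x K_n): nucleosome-level transition matrix,
  conditional on the *destination* domain state; ``t[nu][j, k]`` is
  P(next nuc = k | prev nuc = j, destination domain = nu).
- ``dom_trans`` T (K_d x K_d): domain-level transition matrix, applied only
  at block boundaries; domain states are frozen inside a block.
- ``initial`` P0 (K_n x K_d): joint distribution of the first bin's state
  pair.

The composite transition probability between joint states factorizes as
``delta(mu, nu) * t[nu][j, k]`` away from block boundaries and
``T[mu, nu] * t[nu][j, k]`` at them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import BinarizedTracks, DihmmError, FormatError, ValidationError

MODEL_FORMAT_VERSION = "dihmm-model-1"

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class DiHMMModel:
    """Container for the four parameter families plus structural constants."""

    emissions: np.ndarray  # (K_n, M)
    nuc_trans: np.ndarray  # (K_d, K_n, K_n)
    dom_trans: np.ndarray  # (K_d, K_d)
    initial: np.ndarray  # (K_n, K_d)
    block_size: int
    mark_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "emissions", np.asarray(self.emissions, dtype=np.float64))
        object.__setattr__(self, "nuc_trans", np.asarray(self.nuc_trans, dtype=np.float64))
        object.__setattr__(self, "dom_trans", np.asarray(self.dom_trans, dtype=np.float64))
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=np.float64))
        object.__setattr__(self, "mark_names", tuple(str(m) for m in self.mark_names))
        if self.emissions.ndim != 2:
            raise ValidationError("emissions must be (K_n, M)")
        if self.nuc_trans.ndim != 3:
            raise ValidationError("nuc_trans must be (K_d, K_n, K_n)")
        if self.dom_trans.ndim != 2:
            raise ValidationError("dom_trans must be (K_d, K_d)")
        if self.initial.ndim != 2:
            raise ValidationError("initial must be (K_n, K_d)")
        kn, m = self.emissions.shape
        kd = self.dom_trans.shape[0]
        if self.nuc_trans.shape != (kd, kn, kn):
            raise ValidationError(
                f"nuc_trans shape {self.nuc_trans.shape} inconsistent with K_d={kd}, K_n={kn}"
            )
        if self.dom_trans.shape != (kd, kd):
            raise ValidationError("dom_trans must be square")
        if self.initial.shape != (kn, kd):
            raise ValidationError(
                f"initial shape {self.initial.shape} inconsistent with K_n={kn}, K_d={kd}"
            )
        if len(self.mark_names) != m:
            raise ValidationError(
                f"{len(self.mark_names)} mark names for {m} emission columns"
            )
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")

    @property
    def n_nuc(self) -> int:
        return self.emissions.shape[0]

    @property
    def n_dom(self) -> int:
        return self.dom_trans.shape[0]

    @property
    def n_marks(self) -> int:
        return self.emissions.shape[1]


def validate(model: DiHMMModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid).

    Each entry names the offending parameter family and index; nothing is
    raised, so the function doubles as a diagnostic.
    """
    out: list[str] = []
    E, t, T, P0 = model.emissions, model.nuc_trans, model.dom_trans, model.initial
    for name, arr in (("emissions", E), ("nuc_trans", t), ("dom_trans", T), ("initial", P0)):
        bad = np.argwhere((arr < 0) | (arr > 1) | ~np.isfinite(arr))
        for idx in bad:
            out.append(f"{name}[{', '.join(map(str, idx))}] = {arr[tuple(idx)]} outside [0, 1]")
    for nu in range(model.n_dom):
        rows = t[nu].sum(axis=1)
        for j in np.nonzero(np.abs(rows - 1.0) > _ROW_TOL)[0]:
            out.append(f"nuc_trans[{nu}] row {j} sums to {rows[j]:.12g}, expected 1")
    rows = T.sum(axis=1)
    for mu in np.nonzero(np.abs(rows - 1.0) > _ROW_TOL)[0]:
        out.append(f"dom_trans row {mu} sums to {rows[mu]:.12g}, expected 1")
    total = P0.sum()
    if abs(total - 1.0) > _ROW_TOL:
        out.append(f"initial sums to {total:.12g}, expected 1")
    return out


def composite_transition(
    model: DiHMMModel,
    from_pair: tuple[int, int],
    to_pair: tuple[int, int],
    at_boundary: bool,
) -> float:
    """Transition probability between joint states (j, mu) -> (k, nu).

    Away from block boundaries the domain state cannot change (Kronecker
    delta); at boundaries the domain transition matrix applies first and the
    nucleosome step is taken under the destination domain nu.
    """
    j, mu = from_pair
    k, nu = to_pair
    if not (0 <= j < model.n_nuc and 0 <= k < model.n_nuc):
        raise ValidationError(f"nucleosome state out of range: {j}, {k}")
    if not (0 <= mu < model.n_dom and 0 <= nu < model.n_dom):
        raise ValidationError(f"domain state out of range: {mu}, {nu}")
    if at_boundary:
        return float(model.dom_trans[mu, nu] * model.nuc_trans[nu, j, k])
    if mu != nu:
        return 0.0
    return float(model.nuc_trans[nu, j, k])


# ---------------------------------------------------------------------------
# k-centre initialization
# ---------------------------------------------------------------------------


def _greedy_kcentre(points: np.ndarray, k: int, first: int) -> list[int]:
    """Greedy farthest-point k-centre (2-approximation) on row vectors.

    Euclidean distance; ties in the farthest-point choice break toward the
    lowest row index. Returns centre row indices.
    """
    n = points.shape[0]
    k = min(k, n)
    centres = [first]
    dist = np.linalg.norm(points - points[first], axis=1)
    while len(centres) < k:
        nxt = int(np.argmax(dist))  # argmax returns the first (lowest) maximizer
        if dist[nxt] == 0.0:
            break  # fewer distinct points than centres requested
        centres.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return centres


def init_kcentre(
    tracks: Sequence[BinarizedTracks],
    n_nuc: int,
    n_dom: int,
    block_size: int,
    seed: int = 0,
    pseudocount: float = 1e-6,
) -> DiHMMModel:
    """Initial parameter estimate from a hard two-scale clustering of the bins.

    Nucleosome level: the distinct bin mark-patterns are clustered by greedy
    farthest-point k-centre under Hamming distance, seeded at the most
    frequent pattern (lexicographic tie-break); every bin is assigned to its
    nearest centre. Domain level: each block's nucleosome-state composition
    vector (length K_n) is clustered the same way under Euclidean distance,
    seeded at the block closest to the mean composition. All four parameter
    families are then the pseudocount-smoothed empirical frequencies of the
    hard assignment; emission rows are additionally shrunk toward 0.5 to
    undo the over-confidence of hard assignment.

    ``seed`` is accepted for interface stability; the default procedure is
    fully deterministic and does not consume it.
    """
    del seed  # deterministic procedure
    if not tracks:
        raise ValidationError("at least one track is required")
    marks = tracks[0].mark_names
    for tr in tracks:
        if tr.mark_names != marks:
            raise ValidationError(
                f"inconsistent mark names: {tr.mark_names} vs {marks}"
            )
    X = np.concatenate([tr.data for tr in tracks], axis=0).astype(np.float64)

    # -- nucleosome centres on distinct patterns, most frequent first.
    # Farthest-point selection is dominated by rare noise patterns if every
    # observed pattern is a candidate, so candidates are limited to patterns
    # covering at least a quarter of a state's fair share (1 / (4 K_n)) of
    # bins; if too few qualify, the K_n most frequent patterns are used.
    patterns, inverse, counts = np.unique(
        X, axis=0, return_inverse=True, return_counts=True
    )
    min_count = counts.sum() / (4.0 * n_nuc)
    cand = np.nonzero(counts >= min_count)[0]
    if cand.size < n_nuc:
        cand = np.argsort(-counts, kind="stable")[: min(n_nuc, counts.size)]
        cand = np.sort(cand)
    # np.unique sorts patterns lexicographically, so argmax tie-break is lexicographic
    first = int(np.argmax(counts[cand]))
    centre_rows = [cand[i] for i in _greedy_kcentre(patterns[cand], n_nuc, first)]
    centres = patterns[centre_rows]  # (K_n', M)
    if len(centre_rows) < n_nuc:
        # degenerate: fewer distinct patterns than states; pad by repeating
        reps = n_nuc - len(centre_rows)
        centres = np.vstack([centres, centres[np.arange(reps) % len(centre_rows)]])
    # Hamming distance == squared Euclidean on 0/1 vectors
    d = ((patterns[:, None, :] - centres[None, :, :]) != 0).sum(axis=2)
    pattern_state = np.argmin(d, axis=1)  # ties -> lowest state index
    nuc_assign = pattern_state[inverse]

    # -- per-track block compositions and domain centres
    comps = []
    track_blocks = []
    offset = 0
    for tr in tracks:
        L = tr.num_bins
        a = nuc_assign[offset : offset + L]
        offset += L
        nb = -(-L // block_size)
        c = np.zeros((nb, n_nuc))
        for b in range(nb):
            seg = a[b * block_size : (b + 1) * block_size]
            c[b] = np.bincount(seg, minlength=n_nuc) / seg.size
        comps.append(c)
        track_blocks.append(a)
    allc = np.concatenate(comps, axis=0)
    if allc.shape[0] < n_dom:
        raise ValidationError(
            f"only {allc.shape[0]} blocks available for {n_dom} domain states"
        )
    mean = allc.mean(axis=0)
    first_dom = int(np.argmin(np.linalg.norm(allc - mean, axis=1)))
    dom_centres = allc[_greedy_kcentre(allc, n_dom, first_dom)]
    if dom_centres.shape[0] < n_dom:
        reps = n_dom - dom_centres.shape[0]
        dom_centres = np.vstack(
            [dom_centres, dom_centres[np.arange(reps) % dom_centres.shape[0]]]
        )

    # -- counted parameter estimates under the hard assignment
    E_num = np.full((n_nuc, len(marks)), pseudocount)
    E_den = np.full(n_nuc, 2.0 * pseudocount)
    t_cnt = np.full((n_dom, n_nuc, n_nuc), pseudocount)
    T_cnt = np.full((n_dom, n_dom), pseudocount)
    P0_cnt = np.full((n_nuc, n_dom), pseudocount)
    offset = 0
    for tr, c in zip(tracks, comps):
        L = tr.num_bins
        a = nuc_assign[offset : offset + L]
        offset += L
        dblocks = np.argmin(
            np.linalg.norm(c[:, None, :] - dom_centres[None, :, :], axis=2), axis=1
        )
        dom = np.repeat(dblocks, block_size)[:L]
        np.add.at(E_num, a, tr.data.astype(np.float64))
        np.add.at(E_den, a, 1.0)
        P0_cnt[a[0], dom[0]] += 1.0
        # nucleosome steps credited to the destination bin's domain
        np.add.at(t_cnt, (dom[1:], a[:-1], a[1:]), 1.0)
        np.add.at(T_cnt, (dblocks[:-1], dblocks[1:]), 1.0)
    # Hard assignment estimates the emission of each separating mark from the
    # very bins selected by that mark, which biases the estimate toward 0/1
    # and can strand EM near a deterministic-emission local optimum. Shrink
    # toward the uninformative rate 0.5 (weight 1/4) before refinement.
    E = 0.75 * (E_num / E_den[:, None]) + 0.25 * 0.5
    t = t_cnt / t_cnt.sum(axis=2, keepdims=True)
    T = T_cnt / T_cnt.sum(axis=1, keepdims=True)
    P0 = P0_cnt / P0_cnt.sum()
    return DiHMMModel(
        emissions=E,
        nuc_trans=t,
        dom_trans=T,
        initial=P0,
        block_size=block_size,
        mark_names=marks,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: DiHMMModel, destination) -> None:
    """Write the model as versioned JSON (full double precision)."""
    payload = {
        "format": MODEL_FORMAT_VERSION,
        "n_nuc": model.n_nuc,
        "n_dom": model.n_dom,
        "n_marks": model.n_marks,
        "block_size": model.block_size,
        "mark_names": list(model.mark_names),
        "emissions": model.emissions.tolist(),
        "nuc_trans": model.nuc_trans.tolist(),
        "dom_trans": model.dom_trans.tolist(),
        "initial": model.initial.tolist(),
    }
    if hasattr(destination, "write"):
        json.dump(payload, destination)
    else:
        with open(destination, "w") as fh:
            json.dump(payload, fh, indent=1)


def load_model(source) -> DiHMMModel:
    """Read a model written by :func:`save_model`, checking version and shapes."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"unsupported model format {payload.get('format')!r}, "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    kn, kd, m = payload["n_nuc"], payload["n_dom"], payload["n_marks"]
    arrs = {}
    for key, shape in (
        ("emissions", (kn, m)),
        ("nuc_trans", (kd, kn, kn)),
        ("dom_trans", (kd, kd)),
        ("initial", (kn, kd)),
    ):
        arr = np.asarray(payload[key], dtype=np.float64)
        if arr.shape != shape:
            raise FormatError(f"{key} has shape {arr.shape}, expected {shape}")
        arrs[key] = arr
    try:
        return DiHMMModel(
            block_size=payload["block_size"], mark_names=payload["mark_names"], **arrs
        )
    except DihmmError:
        raise
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model file: {exc}") from exc
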