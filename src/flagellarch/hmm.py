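"""Profile hidden Markov models for domain family search.

A profile HMM is estimated from a multiple alignment (match columns by gap
occupancy, Henikoff position-based sequence weights, background-mixed
pseudocounts) and scored against sequences in *local* alignment mode: the
model may align to any subsequence, with the flanking residues emitted at
background frequencies so they cancel in the log-odds score.

Model topology (one node per match column, L nodes):

* entry: begin -> M_k with probability 1/L for every k;
* exit: every M_k (k < L) carries a fixed early-exit probability
  ``EXIT_PROB`` to end, scaling its learned continue transitions by
  (1 - EXIT_PROB); M_L exits with probability 1;
* inserts I_k (k < L) between consecutive nodes, deletes D_k
  (1 < k < L) for internal skips; transitions among {M, I, D} are learned
  per node with Laplace pseudocounts.

Scores are log2-odds ("bits") against the background.  Forward sums over
all local paths; Viterbi maximises and yields the hit envelope.  E-values
come from an explicit Gumbel fit to forward scores of shuffled database
sequences, so significance is self-contained rather than inherited from an
external calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy import stats

from .seqio import GAP, MultipleAlignment, SequenceRecord
from .scoring import RESIDUE_INDEX

N_AA = 20
_NEG = -1.0e30

#: Early-exit probability from each internal match state in local mode.
EXIT_PROB = 0.1


@dataclass
class EValueCalibration:
    """Gumbel null for forward bit scores of shuffled database sequences."""

    loc: float
    scale: float
    n_db: int

    def evalue(self, bits: float) -> float:
        """Expected number of database hits scoring >= ``bits`` by chance."""
        return float(self.n_db * stats.gumbel_r.sf(bits, self.loc, self.scale))


@dataclass
class ProfileHMM:
    """Position-specific model over L match states (arrays are 1-indexed
    on the node axis; row 0 is unused padding)."""

    name: str
    match_em: np.ndarray          # (L+1, 20)
    insert_em: np.ndarray         # (20,)
    background: np.ndarray        # (20,)
    t_mm: np.ndarray              # (L+1,) M_k -> M_{k+1}, valid 1..L-1
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_id: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    t_di: np.ndarray
    calibration: EValueCalibration | None = field(default=None)

    @property
    def length(self) -> int:
        return self.match_em.shape[0] - 1

    def validate(self) -> None:
        L = self.length
        if L < 1:
            raise ValueError("profile HMM needs at least one match state")
        for k in range(1, L + 1):
            row = self.match_em[k]
            if abs(row.sum() - 1.0) > 1e-9 or np.any(row <= 0):
                raise ValueError(f"match emission row {k} not a positive distribution")
        for vec in (self.insert_em, self.background):
            if abs(vec.sum() - 1.0) > 1e-9 or np.any(vec <= 0):
                raise ValueError("emission vector not a positive distribution")
        for k in range(1, L):
            for tag, total in (
                ("M", self.t_mm[k] + self.t_mi[k] + self.t_md[k]),
                ("I", self.t_im[k] + self.t_ii[k] + self.t_id[k]),
            ):
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{tag} transitions at node {k} sum to {total}")
        for k in range(2, L):
            total = self.t_dm[k] + self.t_dd[k] + self.t_di[k]
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"D transitions at node {k} sum to {total}")

    # -- serialization (plain text, one node per line) ----------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"name = {self.name}\nlength = {self.length}\n")
            fh.write("alphabet = ACDEFGHIKLMNPQRSTVWY\n")
            fh.write("background = " + " ".join(f"{p:.17e}" for p in self.background) + "\n")
            fh.write("insert_em = " + " ".join(f"{p:.17e}" for p in self.insert_em) + "\n")
            fh.write("# node  match_emissions(20)  mm mi md im ii id dm dd di\n")
            for k in range(1, self.length + 1):
                em = " ".join(f"{p:.17e}" for p in self.match_em[k])
                tr = " ".join(
                    f"{v[k]:.17e}"
                    for v in (self.t_mm, self.t_mi, self.t_md, self.t_im,
                              self.t_ii, self.t_id, self.t_dm, self.t_dd, self.t_di)
                )
                fh.write(f"{k} {em} {tr}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ProfileHMM":
        meta: dict[str, str] = {}
        nodes: list[list[float]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, val = line.split("=", 1)
                meta[key.strip()] = val.strip()
            else:
                nodes.append([float(x) for x in line.split()[1:]])
        L = int(meta["length"])
        if len(nodes) != L:
            raise ValueError(f"expected {L} node rows, found {len(nodes)}")
        match_em = np.zeros((L + 1, N_AA))
        trans = np.zeros((9, L + 1))
        for k, row in enumerate(nodes, start=1):
            match_em[k] = row[:N_AA]
            trans[:, k] = row[N_AA:N_AA + 9]
        hmm = cls(
            name=meta.get("name", "hmm"),
            match_em=match_em,
            insert_em=np.array([float(x) for x in meta["insert_em"].split()]),
            background=np.array([float(x) for x in meta["background"].split()]),
            t_mm=trans[0], t_mi=trans[1], t_md=trans[2],
            t_im=trans[3], t_ii=trans[4], t_id=trans[5],
            t_dm=trans[6], t_dd=trans[7], t_di=trans[8],
        )
        hmm.validate()
        return hmm


@dataclass
class DomainHit:
    """A scored, bounded occurrence of a model on a sequence.

    ``bit_score`` is the forward log2-odds of the (possibly partially
    masked) sequence at the time the hit was called; the interval is the
    Viterbi envelope (residues emitted by match/insert states).
    """

    seq_id: str
    start: int
    end: int
    bit_score: float
    evalue: float | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# model construction


def henikoff_weights(msa: MultipleAlignment, match_cols: list[int]) -> np.ndarray:
    """Position-based sequence weights (mean 1) over the match columns."""
    n = msa.n_rows
    w = np.zeros(n)
    for j in match_cols:
        col = msa.column(j)
        types: dict[str, int] = {}
        for ch in col:
            types[ch] = types.get(ch, 0) + 1
        r = len(types)
        for s, ch in enumerate(col):
            w[s] += 1.0 / (r * types[ch])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def build_hmm(msa: MultipleAlignment, match_column_rule: float = 0.5,
              pseudocount_weight: float = 1.0,
              background: np.ndarray | None = None,
              name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction <= ``match_column_rule`` become match states.
    Emissions are Henikoff-weighted counts mixed with the background at
    ``pseudocount_weight``; transitions get Laplace pseudocounts.  Raises
    if no column qualifies as a match state.
    """
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    background = np.asarray(background, dtype=float)
    match_cols = [
        j for j in range(msa.length) if msa.gap_fraction(j) <= match_column_rule
    ]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no column qualifies as a match state")
    weights = henikoff_weights(msa, match_cols)
    is_match = np.zeros(msa.length, dtype=bool)
    is_match[match_cols] = True

    match_counts = np.zeros((L + 1, N_AA))
    insert_counts = np.zeros(N_AA)
    # transition counts per node: from-state x to-state, nodes 0..L
    # (node 0 = begin; transitions into node L+1 = end are dropped later)
    tc = np.zeros((L + 1, 3, 3))  # [node, from {M,I,D}, to {M,I,D}]
    M_, I_, D_ = 0, 1, 2

    for s, (_, row) in enumerate(msa.rows):
        w = weights[s]
        state, node = M_, 0  # begin acts as M_0
        for j, ch in enumerate(row):
            if is_match[j]:
                nxt = M_ if ch != GAP else D_
                tc[node, state, nxt] += w
                node += 1
                state = nxt
                if ch not in (GAP, "X") and nxt == M_:
                    match_counts[node, RESIDUE_INDEX[ch]] += w
            else:
                if ch == GAP:
                    continue
                if state != I_:
                    tc[node, state, I_] += w
                else:
                    tc[node, I_, I_] += w
                state = I_
                if ch != "X":
                    insert_counts[RESIDUE_INDEX[ch]] += w
        # closing transition to end (node L+1) is not modelled explicitly

    # emissions
    match_em = np.zeros((L + 1, N_AA))
    for k in range(1, L + 1):
        mixed = match_counts[k] + pseudocount_weight * background
        match_em[k] = mixed / mixed.sum()
    ins_mixed = insert_counts + max(pseudocount_weight, 1.0) * N_AA * background
    insert_em = ins_mixed / ins_mixed.sum()

    # transitions with Laplace pseudocounts, then structural zeroing
    def norm(counts: np.ndarray, allowed: np.ndarray) -> np.ndarray:
        probs = (counts + 1.0) * allowed
        total = probs.sum()
        return probs / total if total > 0 else allowed / max(allowed.sum(), 1)

    t = {key: np.zeros(L + 1) for key in
         ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di")}
    for k in range(1, L):
        # D_L does not exist: transitions into it are structurally zero
        allow = np.array([1.0, 1.0, 1.0 if k < L - 1 else 0.0])
        pm = norm(tc[k, M_], allow)
        pi = norm(tc[k, I_], allow)
        pd = norm(tc[k, D_], allow)
        t["mm"][k], t["mi"][k], t["md"][k] = pm[M_], pm[I_], pm[D_]
        t["im"][k], t["ii"][k], t["id"][k] = pi[M_], pi[I_], pi[D_]
        t["dm"][k], t["di"][k], t["dd"][k] = pd[M_], pd[I_], pd[D_]

    hmm = ProfileHMM(
        name=name, match_em=match_em, insert_em=insert_em,
        background=background,
        t_mm=t["mm"], t_mi=t["mi"], t_md=t["md"],
        t_im=t["im"], t_ii=t["ii"], t_id=t["id"],
        t_dm=t["dm"], t_dd=t["dd"], t_di=t["di"],
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# scoring kernels


@njit(cache=True)
def _forward_scaled(emo, eio, entry, exitp, amm, ami, amd, aim, aii, aid,
                    adm, add_, adi):
    """Forward in odds space with per-position rescaling.

    All quantities are odds ratios against the background, so the flanking
    (unaligned) residues contribute factor 1 and are carried by the B
    (before-hit) and C (after-hit) states.  Returns log2-odds bits.
    """
    Lp1, np1 = emo.shape
    L = Lp1 - 1
    n = np1 - 1
    prevM = np.zeros(L + 1)
    prevI = np.zeros(L + 1)
    prevD = np.zeros(L + 1)
    curM = np.zeros(L + 1)
    curI = np.zeros(L + 1)
    curD = np.zeros(L + 1)
    B = 1.0
    C = 0.0
    logacc = 0.0
    for i in range(1, n + 1):
        for k in range(1, L + 1):
            acc = B * entry
            if k > 1:
                acc += (prevM[k - 1] * amm[k - 1]
                        + prevI[k - 1] * aim[k - 1]
                        + prevD[k - 1] * adm[k - 1])
            curM[k] = emo[k, i] * acc
        for k in range(1, L):
            curI[k] = eio[i] * (prevM[k] * ami[k] + prevI[k] * aii[k]
                                + prevD[k] * adi[k])
        curD[1] = 0.0
        for k in range(2, L):
            curD[k] = (curM[k - 1] * amd[k - 1] + curI[k - 1] * aid[k - 1]
                       + curD[k - 1] * add_[k - 1])
        ex = 0.0
        for k in range(1, L + 1):
            ex += curM[k] * exitp[k]
        C += ex
        s = B + C
        for k in range(1, L + 1):
            s += curM[k] + curI[k] + curD[k]
        inv = 1.0 / s
        B *= inv
        C *= inv
        for k in range(L + 1):
            prevM[k] = curM[k] * inv
            prevI[k] = curI[k] * inv
            prevD[k] = curD[k] * inv
        logacc += np.log2(s)
    if C <= 0.0:
        return _NEG
    return np.log2(C) + logacc


@njit(cache=True)
def _viterbi_kernel(em, ei, entry, exitv, cmm, cmi, cmd, cim, cii, cid,
                    cdm, cdd, cdi):
    Lp1, np1 = em.shape
    L = Lp1 - 1
    n = np1 - 1
    VM = np.full((L + 1, n + 1), _NEG)
    VI = np.full((L + 1, n + 1), _NEG)
    VD = np.full((L + 1, n + 1), _NEG)
    # backpointers: 0 entry, 1 M, 2 D, 3 I (tie-break order M > D > I)
    PM = np.zeros((L + 1, n + 1), dtype=np.int8)
    PI = np.zeros((L + 1, n + 1), dtype=np.int8)
    PD = np.zeros((L + 1, n + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for k in range(1, L + 1):
            best = entry
            ptr = 0
            if k > 1 and i > 1:
                vm = VM[k - 1, i - 1] + cmm[k - 1]
                vd = VD[k - 1, i - 1] + cdm[k - 1]
                vi = VI[k - 1, i - 1] + cim[k - 1]
                if vm >= best:
                    best = vm
                    ptr = 1
                if vd > best:
                    best = vd
                    ptr = 2
                if vi > best:
                    best = vi
                    ptr = 3
            VM[k, i] = em[k, i] + best
            PM[k, i] = ptr
        for k in range(1, L):
            vm = VM[k, i - 1] + cmi[k]
            vd = VD[k, i - 1] + cdi[k]
            vi = VI[k, i - 1] + cii[k]
            best = vm
            ptr = 1
            if vd > best:
                best = vd
                ptr = 2
            if vi > best:
                best = vi
                ptr = 3
            VI[k, i] = ei[i] + best
            PI[k, i] = ptr
        for k in range(2, L):
            vm = VM[k - 1, i] + cmd[k - 1]
            vd = VD[k - 1, i] + cdd[k - 1]
            vi = VI[k - 1, i] + cid[k - 1]
            best = vm
            ptr = 1
            if vd > best:
                best = vd
                ptr = 2
            if vi > best:
                best = vi
                ptr = 3
            VD[k, i] = best
            PD[k, i] = ptr
    best = _NEG
    bk = 0
    bi = 0
    for i in range(1, n + 1):
        for k in range(1, L + 1):
            v = VM[k, i] + exitv[k]
            if v > best:
                best = v
                bk = k
                bi = i
    return VM, VI, VD, PM, PI, PD, best, bk, bi


def _log_params(hmm: ProfileHMM):
    L = hmm.length
    with np.errstate(divide="ignore"):
        def lg(x):
            out = np.full_like(x, _NEG, dtype=float)
            pos = x > 0
            out[pos] = np.log2(x[pos])
            return out

        tau = EXIT_PROB if L > 1 else 1.0
        cont = math.log2(1.0 - tau) if tau < 1.0 else _NEG
        cmm = lg(hmm.t_mm) + cont
        cmi = lg(hmm.t_mi) + cont
        cmd = lg(hmm.t_md) + cont
        cim, cii, cid = lg(hmm.t_im), lg(hmm.t_ii), lg(hmm.t_id)
        cdm, cdd, cdi = lg(hmm.t_dm), lg(hmm.t_dd), lg(hmm.t_di)
        entry = math.log2(1.0 / L)
        exitv = np.full(L + 1, _NEG)
        if L > 1:
            exitv[1:L] = math.log2(tau)
        exitv[L] = 0.0
    return entry, exitv, cmm, cmi, cmd, cim, cii, cid, cdm, cdd, cdi


def _emission_logodds(hmm: ProfileHMM, residues: str):
    L = hmm.length
    n = len(residues)
    lodds = np.log2(hmm.match_em[1:] / hmm.background)  # (L, 20)
    li = np.log2(hmm.insert_em / hmm.background)
    idx = np.array([RESIDUE_INDEX[c] for c in residues])
    is_x = idx >= N_AA
    safe = np.where(is_x, 0, idx)
    em = np.zeros((L + 1, n + 1))
    ei = np.zeros(n + 1)
    em[1:, 1:] = lodds[:, safe]
    ei[1:] = li[safe]
    em[1:, 1:][:, is_x] = 0.0  # X scores 0 everywhere
    ei[1:][is_x] = 0.0
    return em, ei


def _as_residues(s) -> tuple[str, str]:
    if isinstance(s, SequenceRecord):
        return s.id, s.residues
    return "seq", str(s).upper()


def _linear_params(hmm: ProfileHMM):
    L = hmm.length
    tau = EXIT_PROB if L > 1 else 1.0
    cont = 1.0 - tau
    entry = 1.0 / L
    exitp = np.zeros(L + 1)
    if L > 1:
        exitp[1:L] = tau
    exitp[L] = 1.0
    return (entry, exitp, hmm.t_mm * cont, hmm.t_mi * cont, hmm.t_md * cont,
            hmm.t_im, hmm.t_ii, hmm.t_id, hmm.t_dm, hmm.t_dd, hmm.t_di)


def _emission_odds(hmm: ProfileHMM, residues: str):
    L = hmm.length
    n = len(residues)
    odds = hmm.match_em[1:] / hmm.background  # (L, 20)
    oi = hmm.insert_em / hmm.background
    idx = np.array([RESIDUE_INDEX[c] for c in residues])
    is_x = idx >= N_AA
    safe = np.where(is_x, 0, idx)
    emo = np.zeros((L + 1, n + 1))
    eio = np.zeros(n + 1)
    emo[1:, 1:] = odds[:, safe]
    eio[1:] = oi[safe]
    emo[1:, 1:][:, is_x] = 1.0  # X: odds 1 (scores 0 bits) everywhere
    eio[1:][is_x] = 1.0
    return emo, eio


def forward_score(hmm: ProfileHMM, s) -> float:
    """Forward log2-odds (bits) of the sequence under local alignment mode."""
    _, residues = _as_residues(s)
    emo, eio = _emission_odds(hmm, residues)
    params = _linear_params(hmm)
    return float(_forward_scaled(emo, eio, *params))


def viterbi_decode(hmm: ProfileHMM, s) -> tuple[list[tuple[str, int, int]], DomainHit]:
    """Best local state path and its hit envelope.

    Returns (path, hit): the path is a list of (state, node, residue
    position 1-based; 0 for deletes), the hit interval covers the residues
    emitted by match/insert states.  Tie-breaking prefers M > D > I.
    """
    seq_id, residues = _as_residues(s)
    em, ei = _emission_logodds(hmm, residues)
    params = _log_params(hmm)
    VM, VI, VD, PM, PI, PD, best, bk, bi = _viterbi_kernel(em, ei, *params)
    path: list[tuple[str, int, int]] = []
    state, k, i = "M", int(bk), int(bi)
    while True:
        if state == "M":
            path.append(("M", k, i))
            p = PM[k, i]
            if p == 0:
                break
            state = {1: "M", 2: "D", 3: "I"}[int(p)]
            k -= 1
            i -= 1
        elif state == "I":
            # I_k loops at node k; its predecessors M_k/D_k sit at the same node
            path.append(("I", k, i))
            p = PI[k, i]
            state = {1: "M", 2: "D", 3: "I"}[int(p)]
            i -= 1
        else:  # D
            path.append(("D", k, 0))
            p = PD[k, i]
            state = {1: "M", 2: "D", 3: "I"}[int(p)]
            k -= 1
    path.reverse()
    emitted = [pos for st, _, pos in path if st in ("M", "I") and pos > 0]
    start, end = (emitted[0] - 1, emitted[-1]) if emitted else (0, 0)
    hit = DomainHit(seq_id=seq_id, start=start, end=end, bit_score=float(best))
    if hmm.calibration is not None:
        hit.evalue = hmm.calibration.evalue(float(best))
    return path, hit


def calibrate_evalues(hmm: ProfileHMM, records: list[SequenceRecord],
                      n_shuffles: int = 100, seed: int = 0) -> EValueCalibration:
    """Fit a Gumbel null to forward scores of shuffled database sequences.

    E-value of a score x is ``n_db * P(score >= x)`` under the fit.  The
    calibration is stored on the model and returned.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable fit")
    if not records:
        raise ValueError("empty calibration database")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for t in range(n_shuffles):
        rec = records[t % len(records)]
        shuffled = "".join(rng.permutation(list(rec.residues)))
        scores[t] = forward_score(hmm, shuffled)
    if float(np.std(scores)) < 1e-9:
        raise ValueError("degenerate (zero-variance) shuffled score distribution")
    loc, scale = stats.gumbel_r.fit(scores)
    cal = EValueCalibration(loc=float(loc), scale=float(scale), n_db=len(records))
    hmm.calibration = cal
    return cal


def scan(hmm: ProfileHMM, records: list[SequenceRecord],
         evalue_threshold: float = 0.1, max_hits_per_seq: int = 25
         ) -> list[DomainHit]:
    """Greedy iterative domain search: best hit, mask, repeat.

    Per sequence, the best-scoring domain is decoded, its interval masked
    with X, and the search repeated until the next hit's E-value exceeds
    the threshold.  Hits are non-overlapping and reported in sequence
    order.  Requires a calibrated model.
    """
    if hmm.calibration is None:
        raise ValueError("model must be calibrated before scanning")
    out: list[DomainHit] = []
    for rec in records:
        current = rec.residues
        seq_hits: list[DomainHit] = []
        for _ in range(max_hits_per_seq):
            bits = forward_score(hmm, current)
            ev = hmm.calibration.evalue(bits)
            if ev > evalue_threshold:
                break
            _, hit = viterbi_decode(hmm, SequenceRecord(rec.id, current))
            if hit.end <= hit.start:
                break
            hit.bit_score = bits
            hit.evalue = ev
            seq_hits.append(hit)
            current = (
                current[: hit.start]
                + "X" * (hit.end - hit.start)
                + current[hit.end:]
            )
        seq_hits.sort(key=lambda h: h.start)
        out.extend(seq_hits)
    return out


def write_hits_tsv(hits: list[DomainHit], path: str | Path) -> None:
    from .seqio import write_tsv

    rows = [
        {"id": h.seq_id, "start": h.start, "end": h.end,
         "bits": f"{h.bit_score:.2f}",
         "evalue": "" if h.evalue is None else f"{h.evalue:.3g}"}
        for h in hits
    ]
    write_tsv(rows, path, ["id", "start", "end", "bits", "evalue"])
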