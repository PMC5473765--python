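"""Structural detection of intact LTR retrotransposons.

Strategy: exact k-mer seeds anchor candidate direct-repeat pairs; seeds are
chained by diagonal, extended without gaps (X-drop), and candidate
boundaries are refined to the offsets that recover an exact 4–6 bp target
site duplication (TSD) on both flanks, scored jointly with the ungapped
repeat alignment so a chance flank duplication cannot drag a boundary away.
A final alignment of the two repeat copies provides the reported LTR
identity.  No homology library is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .align import align_pair
from .ioutils import GffRecord


@dataclass(frozen=True)
class DetectorConfig:
    min_ltr: int = 100
    max_ltr: int = 3500
    min_element: int = 1000
    max_element: int = 20000
    min_ltr_identity: float = 0.75
    tsd_window: int = 20
    require_tg_ca: bool = False
    seed_k: int = 20
    diagonal_band: int = 15  # tolerated diagonal drift when chaining seeds

    def __post_init__(self):
        if not self.min_ltr <= self.max_ltr < self.max_element:
            raise ValueError("need min_ltr <= max_ltr < max_element")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class IntactElement:
    contig: str
    ltr5: tuple[int, int]  # 0-based half-open
    ltr3: tuple[int, int]
    internal: tuple[int, int]
    tsd: str | None
    strand: str
    ltr_identity: float
    element_id: str = ""
    score: float = 0.0  # detector ranking score (diagnostic)

    @property
    def start(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]

    def __post_init__(self):
        if not (self.ltr5[1] <= self.internal[0] <= self.internal[1] <= self.ltr3[0]):
            raise ValueError("LTR/internal intervals out of order")


# ---------------------------------------------------------------------------
# seed collection


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int64)
    for i, base in enumerate(b"ACGT"):
        codes[arr == base] = i
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and their start positions (N windows dropped)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    val = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        window = codes[j : j + m]
        val = (val << 2) | np.where(window == 4, 0, window)
        bad |= window == 4
    positions = np.nonzero(~bad)[0]
    return val[positions], positions


def _seed_matches(seq: str, config: DetectorConfig) -> np.ndarray:
    """(diagonal, pos_i) pairs of exact k-mer matches with i < j and
    j - i inside the bounds an LTR-pair start distance can take."""
    codes = _encode(seq)
    vals, positions = _kmer_codes(codes, config.seed_k)
    if len(vals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    sorted_pos = positions[order]
    boundaries = np.nonzero(np.diff(sorted_vals))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(sorted_vals)]))
    d_min = max(config.min_element - config.max_ltr, config.min_ltr)
    d_max = config.max_element - config.min_ltr
    out = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        group = np.sort(sorted_pos[s:e])
        for a in range(len(group) - 1):
            for b in range(a + 1, len(group)):
                d = group[b] - group[a]
                if d > d_max:
                    break
                if d >= d_min:
                    out.append((d, group[a]))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.array(out, dtype=np.int64)
    return arr[np.lexsort((arr[:, 1], arr[:, 0]))]


def _chain_seeds(matches: np.ndarray, config: DetectorConfig) -> list[tuple[int, int, int]]:
    """Group seed matches into candidate repeat pairs.

    Returns (diagonal, i_min, i_max) per chain, where positions are k-mer
    starts on the 5' copy.  Seeds chain when their diagonals differ by at
    most ``diagonal_band`` and their positions stay within an LTR-sized span.
    """
    chains: list[tuple[int, int, int]] = []
    cur_d = None
    cur_lo = cur_hi = 0
    for d, i in matches:
        d = int(d)
        i = int(i)
        if (
            cur_d is not None
            and abs(d - cur_d) <= config.diagonal_band
            and i - cur_hi <= config.max_ltr
            and (i + config.seed_k) - cur_lo <= config.max_ltr + config.diagonal_band
        ):
            cur_hi = max(cur_hi, i)
        else:
            if cur_d is not None:
                chains.append((cur_d, cur_lo, cur_hi))
            cur_d, cur_lo, cur_hi = d, i, i
    if cur_d is not None:
        chains.append((cur_d, cur_lo, cur_hi))
    return chains


# ---------------------------------------------------------------------------
# extension and refinement


def _xdrop_extend(arr: np.ndarray, a: int, b: int, step: int, limit: int, xdrop: int = 12) -> int:
    """Ungapped extension comparing arr[a+t*step] vs arr[b+t*step]; returns the
    number of further columns (beyond the start) kept at the score maximum."""
    score = 0
    best = 0
    best_t = 0
    t = 0
    n = len(arr)
    while True:
        t += 1
        if t > limit:
            break
        pa = a + t * step
        pb = b + t * step
        if pa < 0 or pb < 0 or pa >= n or pb >= n:
            break
        if arr[pa] == arr[pb]:
            score += 1
        else:
            score -= 2
        if score > best:
            best = score
            best_t = t
        elif best - score > xdrop:
            break
    return best_t


def _refine_boundaries(
    arr: np.ndarray,
    seq: str,
    d: int,
    s0: int,
    e0: int,
    config: DetectorConfig,
) -> tuple[int, int, str, float] | None:
    """Search TSD-consistent (element start, outer end) offsets near the
    tentative boundaries.

    Every exact 4–6 bp flank duplication inside the window is scored as
    3*matches - 2*ltr_len + 2*tsd_len (an ungapped alignment score with a TSD
    bonus), so a chance short duplication far from the alignment-supported
    boundary cannot win against the genuine one.  Ties break to the longer
    TSD, then the leftmost start.
    """
    n = len(arr)
    w = config.tsd_window
    best = None
    for s in range(max(s0 - w, 4), min(s0 + w, n - 1) + 1):
        for tsd_len in (6, 5, 4):
            if s - tsd_len < 0:
                continue
            left = seq[s - tsd_len : s]
            if "N" in left:
                continue
            e_lo = max(e0 - w, s + d + config.min_ltr, s + config.min_element)
            e_hi = min(e0 + w, n - tsd_len, s + config.max_element, s + d + min(config.max_ltr, d))
            for e in range(e_lo, e_hi + 1):
                if seq[e : e + tsd_len] != left:
                    continue
                ltr_len = e - s - d
                if ltr_len < config.min_ltr or ltr_len > d:
                    continue
                copy1 = arr[s : s + ltr_len]
                copy2 = arr[s + d : e]
                matches = int(np.count_nonzero(copy1 == copy2))
                if matches / ltr_len < config.min_ltr_identity:
                    continue
                score = 3 * matches - 2 * ltr_len + 2 * tsd_len
                key = (score, tsd_len, -s)
                if best is None or key > best[0]:
                    best = (key, s, e, left)
    if best is None:
        return None
    return best[1], best[2], best[3], float(best[0][0])


def _ltr_unit_in_internal(seq: str, ltr5: tuple[int, int], internal: tuple[int, int],
                          k: int = 15, threshold: float = 0.5) -> bool:
    """True when the internal region contains a further (possibly diverged)
    copy of the LTR unit — the signature of a candidate spanning two distinct
    genomic copies rather than one element."""
    unit = seq[slice(*ltr5)]
    inner = seq[slice(*internal)]
    if len(unit) < k or len(inner) < k:
        return False
    inner_kmers = {inner[i : i + k] for i in range(len(inner) - k + 1)}
    covered = np.zeros(len(unit), dtype=bool)
    for i in range(len(unit) - k + 1):
        if unit[i : i + k] in inner_kmers:
            covered[i : i + k] = True
    return covered.mean() >= threshold


def _candidate_from_chain(
    arr: np.ndarray, seq: str, contig: str, chain: tuple[int, int, int], config: DetectorConfig
) -> IntactElement | None:
    d, lo, hi = chain
    k = config.seed_k
    left = _xdrop_extend(arr, lo, lo + d, -1, limit=config.max_ltr)
    right = _xdrop_extend(
        arr, hi + k - 1, hi + k - 1 + d, +1,
        limit=min(config.max_ltr, d - (hi + k - lo)),
    )
    s0 = lo - left
    b5 = hi + k + right
    if b5 - s0 > config.max_ltr + config.tsd_window:
        return None
    refined = _refine_boundaries(arr, seq, d, s0, b5 + d, config)
    if refined is None:
        return None
    s, e, tsd, score = refined
    ltr_len = e - s - d
    ltr5 = (s, s + ltr_len)
    ltr3 = (s + d, e)
    if ltr5[1] > ltr3[0]:  # overlapping repeat copies are not an LTR pair
        return None
    if config.require_tg_ca and not (seq[s : s + 2] == "TG" and seq[e - 2 : e] == "CA"):
        return None
    if _ltr_unit_in_internal(seq, ltr5, (ltr5[1], ltr3[0])):
        return None
    # authoritative identity from a real alignment of the two copies
    stats = align_pair(seq[slice(*ltr5)], seq[slice(*ltr3)])
    if stats.identity < config.min_ltr_identity:
        return None
    return IntactElement(
        contig=contig,
        ltr5=ltr5,
        ltr3=ltr3,
        internal=(ltr5[1], ltr3[0]),
        tsd=tsd,
        strand="+",
        ltr_identity=round(stats.identity, 6),
        score=score,
    )


def _conflicts(a: IntactElement, b: IntactElement) -> bool:
    """Overlap that is not a clean nesting inside an internal region."""
    if a.end <= b.start or a.start >= b.end:
        return False
    a_inside_b = b.internal[0] <= a.start and a.end <= b.internal[1]
    b_inside_a = a.internal[0] <= b.start and b.end <= a.internal[1]
    return not (a_inside_b or b_inside_a)


def _resolve_overlaps(candidates: list[IntactElement]) -> list[IntactElement]:
    """Select a conflict-free candidate subset, maximizing the NUMBER of
    elements first and alignment score second.

    Two separate genomic copies of one family paired across elements produce
    a single long artifact candidate that conflicts with both genuine
    candidates it spans; count-dominant selection always prefers the two
    genuine elements.  A candidate one of whose LTR copies essentially
    contains another candidate's whole span is additionally dropped outright.
    Full nesting inside an accepted element's internal region is allowed.
    """
    pruned = []
    for cand in candidates:
        container = False
        for other in candidates:
            if other is cand:
                continue
            length = other.end - other.start
            for ltr in (cand.ltr5, cand.ltr3):
                covered = min(ltr[1], other.end) - max(ltr[0], other.start)
                if covered >= 0.9 * length:
                    container = True
                    break
            if container:
                break
        if not container:
            pruned.append(cand)

    # conflict components
    n = len(pruned)
    adj = [set() for _ in range(n)]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _conflicts(pruned[i], pruned[j]):
                adj[i].add(j)
                adj[j].add(i)
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    accepted: list[IntactElement] = []
    big_weight = 1_000_000.0  # count dominates score
    for members in components.values():
        if len(members) == 1:
            accepted.append(pruned[members[0]])
            continue
        if len(members) <= 16:
            accepted.extend(
                pruned[i] for i in _exact_mwis(members, adj, pruned, big_weight)
            )
        else:  # greedy fallback for pathological regions
            chosen: list[int] = []
            for i in sorted(
                members,
                key=lambda i: (pruned[i].score, pruned[i].ltr_identity, -pruned[i].start),
                reverse=True,
            ):
                if all(j not in adj[i] for j in chosen):
                    chosen.append(i)
            accepted.extend(pruned[i] for i in chosen)
    accepted.sort(key=lambda c: (c.contig, c.start, c.end))
    return accepted


def _exact_mwis(members: list[int], adj: list[set[int]], cands: list[IntactElement],
                big_weight: float) -> list[int]:
    """Exact maximum-weight independent set over one small conflict component."""
    index = {m: k for k, m in enumerate(members)}
    masks = []
    for m in members:
        mask = 0
        for other in adj[m]:
            if other in index:
                mask |= 1 << index[other]
        masks.append(mask)
    weights = [big_weight + cands[m].score for m in members]
    best_weight = -1.0
    best_set: int = 0
    size = len(members)
    for subset in range(1 << size):
        ok = True
        total = 0.0
        remaining = subset
        while remaining:
            bit = remaining & -remaining
            k = bit.bit_length() - 1
            if masks[k] & subset:
                ok = False
                break
            total += weights[k]
            remaining ^= bit
        if ok and total > best_weight:
            best_weight = total
            best_set = subset
    return [members[k] for k in range(size) if best_set >> k & 1]


def find_intact_elements(
    genome: str | Mapping[str, str], config: DetectorConfig | None = None
) -> list[IntactElement]:
    """Detect direct-repeat pairs with a shared TSD across one or more contigs.

    Output is deterministic, coordinate-sorted, and may include nested
    elements (an element wholly inside another's internal region).
    """
    config = config or DetectorConfig()
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    elements: list[IntactElement] = []
    for contig, seq in contigs.items():
        if not seq:
            continue
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {contig}: unexpected characters {sorted(bad)}")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        matches = _seed_matches(seq, config)
        candidates = []
        seen: set[tuple] = set()
        for chain in _chain_seeds(matches, config):
            cand = _candidate_from_chain(arr, seq, contig, chain, config)
            if cand is None:
                continue
            key = (cand.ltr5, cand.ltr3)
            if key not in seen:
                seen.add(key)
                candidates.append(cand)
        elements.extend(_resolve_overlaps(candidates))
    elements.sort(key=lambda c: (c.contig, c.start, c.end))
    for i, el in enumerate(elements):
        el.element_id = f"RC{i + 1:05d}"
    return elements


# ---------------------------------------------------------------------------
# tandem-repeat false positives


def remove_tandem_false_positives(
    candidates: list[IntactElement], genome: str | Mapping[str, str], k: int = 15
) -> list[IntactElement]:
    """Drop candidates whose internal region is itself mostly (>= 80%) covered
    by further copies of the repeat unit — the signature of a long tandem
    array masquerading as an LTR pair."""
    contigs = {"chr1": genome} if isinstance(genome, str) else dict(genome)
    kept = []
    for cand in candidates:
        seq = contigs[cand.contig].upper()
        unit = seq[slice(*cand.ltr5)]
        internal = seq[slice(*cand.internal)]
        if len(internal) == 0:
            # zero-length internal: two abutting repeats, i.e. a tandem pair
            continue
        if len(unit) < k or len(internal) < k:
            kept.append(cand)
            continue
        unit_kmers = {unit[i : i + k] for i in range(len(unit) - k + 1)}
        covered = np.zeros(len(internal), dtype=bool)
        for i in range(len(internal) - k + 1):
            if internal[i : i + k] in unit_kmers:
                covered[i : i + k] = True
        if covered.mean() < 0.80:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# GFF3 output


def elements_to_gff(elements: Iterable[IntactElement]) -> list[GffRecord]:
    """Parent LTR_retrotransposon features with LTR and TSD children
    (1-based inclusive coordinates)."""
    records: list[GffRecord] = []
    for el in elements:
        ident = el.element_id or f"{el.contig}:{el.start}-{el.end}"
        records.append(
            GffRecord(
                seqid=el.contig,
                source="retrochrono-detect",
                type="LTR_retrotransposon",
                start=el.start + 1,
                end=el.end,
                score=f"{el.ltr_identity:.4f}",
                strand=el.strand,
                attributes={"ID": ident, "ltr_identity": f"{el.ltr_identity:.4f}"},
            )
        )
        for name, iv in (("five_prime", el.ltr5), ("three_prime", el.ltr3)):
            records.append(
                GffRecord(
                    seqid=el.contig,
                    source="retrochrono-detect",
                    type="long_terminal_repeat",
                    start=iv[0] + 1,
                    end=iv[1],
                    strand=el.strand,
                    attributes={"Parent": ident, "end_type": name},
                )
            )
        if el.tsd:
            records.append(
                GffRecord(
                    seqid=el.contig,
                    source="retrochrono-detect",
                    type="target_site_duplication",
                    start=el.start - len(el.tsd) + 1,
                    end=el.start,
                    strand=el.strand,
                    attributes={"Parent": ident, "tsd": el.tsd},
                )
            )
    return records


def set_strand(element: IntactElement, strand: str) -> IntactElement:
    """Direct repeats are strand-symmetric; strand is only assigned once the
    taxonomy stage sees the pol-domain orientation."""
    return replace(element, strand=strand)
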