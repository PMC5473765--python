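"""Read-depth copy-number estimation over a deduplicated LTR library, plus
homology annotation of solo LTRs and fragments.

Reads map by exact k-mer seeding followed by ungapped verification; a read
maps when some placement has at most ``max_mismatch_per_100bp`` mismatches
per 100 bp of overlap, and multi-mapped reads contribute fractional weight
1/n_best to each equal-best placement.  Per-representative mean depth is
normalized by the genome-wide mean depth (total read bases / genome length),
the copy-number proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .align import align_pair
from .ioutils import GffRecord, revcomp
from .synth import ReadSet


@dataclass
class LTRRepresentative:
    name: str
    family_id: str
    sequence: str
    collapsed: list[str] = field(default_factory=list)  # member labels absorbed


@dataclass
class LTRLibrary:
    representatives: list[LTRRepresentative]
    dedupe_identity: float
    min_length: int
    n_dropped_short: int = 0

    def __iter__(self):
        return iter(self.representatives)

    def __len__(self):
        return len(self.representatives)


@dataclass
class Placement:
    rep_index: int
    position: int  # 0-based offset of the read's first base on the rep (may be <0)
    strand: str
    mismatches: int
    overlap: int
    weight: float = 0.0


@dataclass
class DepthProfile:
    rep_names: list[str]
    raw_depth: np.ndarray  # mean per-base depth per representative
    normalized_depth: np.ndarray
    mapped_read_count: np.ndarray  # fractional (weighted) read counts
    genome_mean_depth: float
    family_depth: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# library construction


def build_ltr_library(
    ltrs: Sequence[tuple[str, str, str]] | Mapping[str, tuple[str, str]],
    dedupe_identity: float = 0.95,
    min_length: int = 150,
) -> LTRLibrary:
    """Greedy longest-first redundancy removal.

    ``ltrs``: (label, family_id, sequence) triples.  Each sequence joins the
    first existing representative with identity >= dedupe_identity computed
    over the shorter sequence's length; otherwise it founds a new
    representative.  Inputs shorter than ``min_length`` are dropped (their
    count is recorded).
    """
    if isinstance(ltrs, Mapping):
        items = [(label, fam, seq) for label, (fam, seq) in sorted(ltrs.items())]
    else:
        items = list(ltrs)
    n_short = sum(1 for _, _, seq in items if len(seq) < min_length)
    usable = [entry for entry in items if len(entry[2]) >= min_length]
    # longest first; ties by label for determinism
    usable.sort(key=lambda entry: (-len(entry[2]), entry[0]))
    reps: list[LTRRepresentative] = []
    for label, family, seq in usable:
        placed = False
        for rep in reps:
            stats = align_pair(seq, rep.sequence)
            shorter = min(len(seq), len(rep.sequence))
            if shorter and stats.matches / shorter >= dedupe_identity:
                rep.collapsed.append(label)
                placed = True
                break
        if not placed:
            reps.append(
                LTRRepresentative(
                    name=label, family_id=family, sequence=seq, collapsed=[label]
                )
            )
    return LTRLibrary(
        representatives=reps,
        dedupe_identity=dedupe_identity,
        min_length=min_length,
        n_dropped_short=n_short,
    )


# ---------------------------------------------------------------------------
# read mapping


def _build_index(library: LTRLibrary, k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, rep in enumerate(library.representatives):
        seq = rep.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ri, i))
    return index


def _verify(
    read: np.ndarray, rep: np.ndarray, position: int, min_overlap: int
) -> tuple[int, int] | None:
    """Mismatches and overlap for an ungapped placement (read may overhang)."""
    read_len = len(read)
    lo = max(0, -position)
    hi = min(read_len, len(rep) - position)
    overlap = hi - lo
    if overlap < min_overlap:
        return None
    a = read[lo:hi]
    b = rep[position + lo : position + hi]
    mismatches = int(np.count_nonzero(a != b))
    return mismatches, overlap


def map_reads(
    reads: ReadSet | Iterable[str],
    library: LTRLibrary,
    max_mismatch_per_100bp: float = 2.0,
    seed_k: int = 31,
    min_overlap: int = 31,
) -> list[list[Placement]]:
    """All equal-best ungapped placements per read (empty list = unmapped).

    Placement quality is the number of matching bases (overlap minus
    mismatches); all placements attaining the maximum share weight 1/n_best.
    """
    sequences = list(reads.sequences()) if isinstance(reads, ReadSet) else list(reads)
    index = _build_index(library, seed_k)
    rep_arrays = [
        np.frombuffer(rep.sequence.encode("ascii"), dtype=np.uint8)
        for rep in library.representatives
    ]
    out: list[list[Placement]] = []
    for seq in sequences:
        read_len = len(seq)
        if read_len < seed_k:
            out.append([])
            continue
        placements: dict[tuple[int, int, str], Placement] = {}
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else revcomp(seq)
            arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            seed_positions = sorted(
                {0, (read_len - seed_k) // 2, read_len - seed_k}
            )
            for sp in seed_positions:
                for ri, hit_pos in index.get(oriented[sp : sp + seed_k], ()):
                    position = hit_pos - sp
                    key = (ri, position, strand)
                    if key in placements:
                        continue
                    verdict = _verify(arr, rep_arrays[ri], position, min_overlap)
                    if verdict is None:
                        continue
                    mismatches, overlap = verdict
                    if mismatches > max_mismatch_per_100bp * overlap / 100.0:
                        continue
                    placements[key] = Placement(
                        rep_index=ri,
                        position=position,
                        strand=strand,
                        mismatches=mismatches,
                        overlap=overlap,
                    )
        if not placements:
            out.append([])
            continue
        best_quality = max(p.overlap - p.mismatches for p in placements.values())
        winners = sorted(
            (
                p
                for p in placements.values()
                if p.overlap - p.mismatches == best_quality
            ),
            key=lambda p: (p.rep_index, p.position, p.strand),
        )
        weight = 1.0 / len(winners)
        for p in winners:
            p.weight = weight
        out.append(winners)
    return out


# ---------------------------------------------------------------------------
# depth


def depth_profile(
    hit_sets: list[list[Placement]],
    library: LTRLibrary,
    genome_mean_depth: float,
) -> DepthProfile:
    """Weighted per-base depth per representative, normalized by genome-wide
    mean depth; family depth is the length-weighted mean over the family's
    representatives."""
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")
    arrays = [np.zeros(len(rep.sequence)) for rep in library.representatives]
    counts = np.zeros(len(library.representatives))
    for placements in hit_sets:
        for p in placements:
            lo = max(0, p.position)
            hi = p.position + p.overlap + max(0, -p.position)
            hi = min(hi, len(arrays[p.rep_index]))
            arrays[p.rep_index][lo:hi] += p.weight
            counts[p.rep_index] += p.weight
    raw = np.array([arr.mean() if len(arr) else 0.0 for arr in arrays])
    normalized = raw / genome_mean_depth
    family_base: dict[str, float] = {}
    family_len: dict[str, int] = {}
    for rep, r in zip(library.representatives, normalized):
        family_base[rep.family_id] = family_base.get(rep.family_id, 0.0) + r * len(
            rep.sequence
        )
        family_len[rep.family_id] = family_len.get(rep.family_id, 0) + len(rep.sequence)
    family_depth = {
        fam: family_base[fam] / family_len[fam] for fam in sorted(family_base)
    }
    return DepthProfile(
        rep_names=[rep.name for rep in library.representatives],
        raw_depth=raw,
        normalized_depth=normalized,
        mapped_read_count=counts,
        genome_mean_depth=genome_mean_depth,
        family_depth=family_depth,
    )


def genome_mean_depth_from_reads(reads: ReadSet, genome_length: int) -> float:
    """Genome-wide mean depth from read arithmetic: total bases / length."""
    total = sum(len(s) for s in reads.sequences())
    return total / genome_length


# ---------------------------------------------------------------------------
# homology annotation (solo LTRs / fragments)


def _genome_hits(
    genome: str, rep: LTRRepresentative, k: int, min_identity: float, min_length: int
) -> list[tuple[int, int, float]]:
    """Seed-and-extend ungapped hits of one representative on the genome."""
    seq = rep.sequence
    if len(seq) < k:
        return []
    rep_kmers: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        rep_kmers.setdefault(seq[i : i + k], []).append(i)
    diag_hits: dict[int, list[int]] = {}  # diagonal -> genome positions
    for gpos in range(len(genome) - k + 1):
        kmer = genome[gpos : gpos + k]
        if kmer in rep_kmers:
            for rpos in rep_kmers[kmer]:
                diag_hits.setdefault(gpos - rpos, []).append(gpos)
    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    rarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits = []
    for diag, positions in sorted(diag_hits.items()):
        positions.sort()
        # merge runs of seeds on the same diagonal into one hit
        run_start = positions[0]
        prev = positions[0]
        runs = []
        for pos in positions[1:]:
            if pos - prev > len(seq):
                runs.append((run_start, prev))
                run_start = pos
            prev = pos
        runs.append((run_start, prev))
        for g_lo, g_hi in runs:
            r_lo = g_lo - diag
            r_hi = g_hi - diag + k
            # clip the full-unit projection onto the genome
            g_start = max(0, diag)
            g_end = min(len(garr), diag + len(seq))
            span = g_end - g_start
            if span < min_length:
                continue
            a = garr[g_start:g_end]
            b = rarr[g_start - diag : g_end - diag]
            identity = float(np.mean(a == b))
            if identity >= min_identity:
                hits.append((g_start, g_end, identity))
            else:
                # fall back to just the seeded run
                g_start2, g_end2 = g_lo, g_hi + k
                if g_end2 - g_start2 >= min_length:
                    a = garr[g_start2:g_end2]
                    b = rarr[g_start2 - diag : g_end2 - diag]
                    identity = float(np.mean(a == b))
                    if identity >= min_identity:
                        hits.append((g_start2, g_end2, identity))
    return _merge_intervals(hits)


def _merge_intervals(hits: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    if not hits:
        return []
    hits.sort()
    merged = [hits[0]]
    for s, e, ident in hits[1:]:
        ms, me, mident = merged[-1]
        if s <= me:
            merged[-1] = (ms, max(me, e), max(mident, ident))
        else:
            merged.append((s, e, ident))
    return merged


def _has_flanking_tsd(genome: str, start: int, end: int, window: int = 5) -> bool:
    for ds in range(-window, window + 1):
        s = start + ds
        for tsd_len in (6, 5, 4):
            if s - tsd_len < 0:
                continue
            left = genome[s - tsd_len : s]
            for de in range(-window, window + 1):
                e = end + de
                if e + tsd_len <= len(genome) and genome[e : e + tsd_len] == left:
                    return True
    return False


def annotate_homologous_copies(
    genome: str,
    library: LTRLibrary,
    intact_elements: Sequence | None = None,
    min_identity: float = 0.80,
    min_length: int = 100,
    seed_k: int = 15,
    contig: str = "chr1",
    max_element: int = 20000,
) -> list[GffRecord]:
    """Homology search of the LTR library against the genome.

    Hits overlapping a detected intact element are labeled intact-member;
    isolated LTR-sized hits with a flanking TSD and no paired LTR hit of the
    same family within element range are solo LTRs; everything else is a
    fragment.
    """
    if not len(library):
        raise ValueError("library is empty")
    genome = genome.upper()
    intact_spans = [
        (el.start, el.end) for el in (intact_elements or [])
    ]
    all_hits: list[tuple[int, int, float, str]] = []
    for rep in library.representatives:
        for s, e, ident in _genome_hits(genome, rep, seed_k, min_identity, min_length):
            all_hits.append((s, e, ident, rep.family_id))
    all_hits.sort()
    records = []
    for idx, (s, e, ident, family) in enumerate(all_hits):
        label = "fragment"
        if any(s < ie and e > istart for istart, ie in intact_spans):
            label = "intact_member"
        else:
            paired = any(
                other_family == family
                and (os, oe) != (s, e)
                and abs(os - s) <= max_element
                for os, oe, _, other_family in all_hits
            )
            if not paired and _has_flanking_tsd(genome, s, e):
                label = "solo_ltr"
        records.append(
            GffRecord(
                seqid=contig,
                source="retrochrono-abundance",
                type={"intact_member": "LTR_retrotransposon",
                      "solo_ltr": "solo_LTR",
                      "fragment": "transposon_fragment"}[label],
                start=s + 1,
                end=e,
                score=f"{ident:.4f}",
                strand="+",
                attributes={"ID": f"hom{idx:05d}", "family": family, "label": label},
            )
        )
    return records


def family_sequence_lengths(records: Iterable[GffRecord]) -> dict[str, int]:
    """Total annotated sequence length per family (Table-1-style statistic)."""
    out: dict[str, int] = {}
    for rec in records:
        family = rec.attributes.get("family", "?")
        out[family] = out.get(family, 0) + (rec.end - rec.start + 1)
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# depth-vs-count validation


@dataclass
class DepthProxyReport:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    valid: bool


def validate_depth_proxy(
    family_depth: Mapping[str, float], family_counts: Mapping[str, float]
) -> DepthProxyReport:
    """Pearson correlation (and regression) of per-family normalized depth
    against intact counts — the synthetic analogue of the depth-vs-count
    validation."""
    families = sorted(set(family_depth) & set(family_counts))
    if len(families) < 3:
        raise ValueError("need at least 3 families")
    x = np.array([float(family_counts[f]) for f in families])
    y = np.array([float(family_depth[f]) for f in families])
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return DepthProxyReport(
            r=float("nan"), p_value=float("nan"), n=len(families),
            slope=float("nan"), intercept=float("nan"), valid=False,
        )
    r, p = _scipy_stats.pearsonr(x, y)
    reg = _scipy_stats.linregress(x, y)
    return DepthProxyReport(
        r=float(r), p_value=float(p), n=len(families),
        slope=float(reg.slope), intercept=float(reg.intercept), valid=True,
    )
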