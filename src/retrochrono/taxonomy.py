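"""Superfamily classification by pol-domain order and family clustering by
5'-LTR identity.

Classification follows the domain-order rule: PR before IN before RT is
Ty1-copia, PR before RT before IN is Ty3-gypsy, anything missing RT (or in
a different order) is unclassified.  Families are single-linkage clusters
over the pairwise 5'-LTR graph with an edge when global-alignment identity
exceeds ``min_identity`` and the aligned span covers at least
``min_reciprocal_coverage`` of BOTH LTRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .align import align_pair, align_protein_local
from .ioutils import revcomp

SUPERFAMILIES = ("copia", "gypsy", "unclassified")
POL_DOMAINS = ("GAG", "PR", "IN", "RT")


@dataclass
class DomainHit:
    domain: str
    start: int  # nucleotide coords on the internal region, 0-based half-open
    end: int
    score: float
    frame: int  # 0..2
    strand: str  # + | -
    identity: float = 0.0

    def __post_init__(self):
        if self.domain not in POL_DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


@dataclass(frozen=True)
class ClusteringConfig:
    min_identity: float = 0.80  # strict: identity must EXCEED this
    min_reciprocal_coverage: float = 0.50

    def __post_init__(self):
        for value in (self.min_identity, self.min_reciprocal_coverage):
            if not 0 < value <= 1:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class Family:
    family_id: str  # OAL-style rank name, assigned by name_and_rank_families
    superfamily: str
    members: list[str]
    n_intact: int
    copy_class: str = ""  # high | low | single

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")


# ---------------------------------------------------------------------------
# domain scanning


def _six_frames(seq: str) -> list[tuple[str, int, str]]:
    """(protein, frame, strand) for all six reading frames."""
    frames = []
    rc = revcomp(seq)
    for frame in range(3):
        for strand, s in (("+", seq), ("-", rc)):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append((str(Seq(sub).translate()), frame, strand))
    return frames


def _aa_to_nt(aa_start: int, aa_end: int, frame: int, strand: str, seq_len: int) -> tuple[int, int]:
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return seq_len - nt_end, seq_len - nt_start


def scan_domains(
    internal: str,
    references: Mapping[str, Sequence[str] | str],
    min_score: float = 100.0,
    min_coverage: float = 0.30,
) -> list[DomainHit]:
    """Translated similarity search of the internal region against per-domain
    protein references (six-frame translation + local protein alignment).

    Returns the best non-overlapping hit per domain, coordinate-ordered;
    hits below ``min_score`` or covering less than ``min_coverage`` of the
    reference are discarded.
    """
    if not internal:
        return []
    refs = {
        domain: ([seqs] if isinstance(seqs, str) else list(seqs))
        for domain, seqs in references.items()
    }
    for domain, seqs in refs.items():
        if not seqs:
            raise ValueError(f"no references supplied for domain {domain}")
    frames = _six_frames(internal.upper())
    raw_hits: list[DomainHit] = []
    for domain, seqs in refs.items():
        best: DomainHit | None = None
        for ref in seqs:
            for protein, frame, strand in frames:
                hit = align_protein_local(protein, ref)
                if hit is None or hit.score < min_score:
                    continue
                if (hit.ref_end - hit.ref_start) / len(ref) < min_coverage:
                    continue
                nt = _aa_to_nt(hit.query_start, hit.query_end, frame, strand, len(internal))
                cand = DomainHit(
                    domain=domain,
                    start=nt[0],
                    end=nt[1],
                    score=hit.score,
                    frame=frame,
                    strand=strand,
                    identity=hit.identity,
                )
                if best is None or cand.score > best.score:
                    best = cand
        if best is not None:
            raw_hits.append(best)
    # greedy non-overlap across domains, strongest first
    accepted: list[DomainHit] = []
    for hit in sorted(raw_hits, key=lambda h: (-h.score, h.domain)):
        if all(hit.end <= other.start or hit.start >= other.end for other in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return accepted


def classify_superfamily(hits: Sequence[DomainHit]) -> str:
    """Domain-order rule: PR<IN<RT -> copia, PR<RT<IN -> gypsy, else
    unclassified (including any element lacking RT).

    Hits must be coordinate-ordered; on the minus strand the biological
    order is the reverse of the coordinate order.
    """
    if not hits:
        return "unclassified"
    ordered = sorted(hits, key=lambda h: h.start)
    minus = sum(1 for h in ordered if h.strand == "-")
    if minus > len(ordered) - minus:
        ordered = ordered[::-1]
    order = [h.domain for h in ordered if h.domain in ("PR", "IN", "RT")]
    if order == ["PR", "IN", "RT"]:
        return "copia"
    if order == ["PR", "RT", "IN"]:
        return "gypsy"
    return "unclassified"


# ---------------------------------------------------------------------------
# family clustering


def _shared_kmers(a: str, b: str, k: int = 10) -> int:
    if len(a) < k or len(b) < k:
        return 0
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i : i + k] in kmers)


def cluster_families(
    ltrs: Mapping[str, str],
    config: ClusteringConfig | None = None,
    superfamilies: Mapping[str, str] | None = None,
) -> list[Family]:
    """Single-linkage clustering of elements by their 5'-LTR sequences.

    ``ltrs`` maps element id -> 5'-LTR sequence.  An edge joins two elements
    when identity > min_identity (strict, per the >80% rule) and the aligned
    span is at least min_reciprocal_coverage of both LTR lengths.  Connected
    components are families; the family superfamily is the majority vote of
    member superfamilies with ties going to unclassified.
    """
    config = config or ClusteringConfig()
    ids = sorted(ltrs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i_pos, a in enumerate(ids):
        for b in ids[i_pos + 1 :]:
            if find(a) == find(b):
                continue
            # cheap prefilter: >80% identity implies many shared 10-mers
            if _shared_kmers(ltrs[a], ltrs[b]) < 3:
                continue
            stats = align_pair(ltrs[a], ltrs[b])
            if (
                stats.identity > config.min_identity
                and stats.coverage_a >= config.min_reciprocal_coverage
                and stats.coverage_b >= config.min_reciprocal_coverage
            ):
                union(a, b)

    groups: dict[str, list[str]] = {}
    for element_id in ids:
        groups.setdefault(find(element_id), []).append(element_id)

    families = []
    for root in sorted(groups):
        members = sorted(groups[root])
        superfamily = "unclassified"
        if superfamilies:
            votes: dict[str, int] = {}
            for member in members:
                label = superfamilies.get(member, "unclassified")
                votes[label] = votes.get(label, 0) + 1
            top = max(votes.values())
            winners = sorted(label for label, v in votes.items() if v == top)
            superfamily = winners[0] if len(winners) == 1 else "unclassified"
        families.append(
            Family(
                family_id=root,  # provisional: renamed by name_and_rank_families
                superfamily=superfamily,
                members=members,
                n_intact=len(members),
            )
        )
    return families


def copy_class_for(n_intact: int) -> str:
    """Printed class bounds: high-copy (>20), low-copy (2–20), single-copy."""
    if n_intact > 20:
        return "high"
    if n_intact >= 2:
        return "low"
    return "single"


def name_and_rank_families(
    families: Sequence[Family],
    counts_by_genome: Mapping[str, Mapping[str, int]] | None = None,
    reference_genome_label: str | None = None,
    prefix: str = "OAL",
) -> list[Family]:
    """Rank families by descending intact count in the reference genome and
    assign OAL-style names (OAL001, OAL002, ...) and copy classes.

    ``counts_by_genome`` maps provisional family_id -> {genome: count}; when
    absent, each family's total member count is used.  Ties break by total
    count, then by the lexicographically smallest member id.
    """

    def ref_count(family: Family) -> int:
        if counts_by_genome is None or reference_genome_label is None:
            return family.n_intact
        return counts_by_genome.get(family.family_id, {}).get(reference_genome_label, 0)

    def total_count(family: Family) -> int:
        if counts_by_genome is None:
            return family.n_intact
        return sum(counts_by_genome.get(family.family_id, {}).values())

    ranked = sorted(
        families,
        key=lambda f: (-ref_count(f), -total_count(f), min(f.members)),
    )
    out = []
    for rank, family in enumerate(ranked, 1):
        out.append(
            Family(
                family_id=f"{prefix}{rank:03d}",
                superfamily=family.superfamily,
                members=list(family.members),
                n_intact=family.n_intact,
                copy_class=copy_class_for(ref_count(family)),
            )
        )
    return out
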