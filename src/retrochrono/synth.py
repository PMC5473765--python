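"""Synthetic genomes with planted LTR retrotransposons and ground truth.

The generator enforces the core dating assumption — the two LTRs of an
element are identical at insertion — and then ages every copy by applying
independent Jukes–Cantor substitutions to each LTR (and to the internal
region) on a branch of length ``mutation_rate x age``.  Under this scheme the
expected proportion of mismatched sites between the two LTRs of a copy of age
T is (3/4)(1 - exp(-8 r T / 3)), whose JC-corrected divergence is exactly
K = 2 r T.

Intact copies carry the element between two exact copies of a 4–6 bp target
site duplication (TSD); solo LTRs are the unequal-recombination product (a
single LTR, still flanked by the TSD); fragments are intact copies with a
contiguous 40–90% span deleted.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import ioutils
from .ioutils import GffRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid (standard table, stops excluded)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}.items():
    _CODONS.setdefault(_aa, []).append(_codon)

_DOMAIN_LENGTHS = {"GAG": 100, "PR": 70, "IN": 100, "RT": 150}
DOMAINS = ("GAG", "PR", "IN", "RT")


class PlacementError(RuntimeError):
    """Background too small to host the requested copies."""


def _hash_rng(*parts: object) -> np.random.Generator:
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def domain_references() -> dict[str, str]:
    """Canonical amino-acid reference sequence per pol/gag domain.

    Deterministic; shared by all families (each family plants a slightly
    diverged variant, see :func:`family_domain_proteins`).
    """
    refs = {}
    for domain, length in _DOMAIN_LENGTHS.items():
        rng = _hash_rng("domain-ref", domain)
        refs[domain] = "".join(
            _AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), length)
        )
    return refs


def family_domain_proteins(family_id: str, divergence: float = 0.08) -> dict[str, str]:
    """Per-family planted domain proteins: the canonical references with a
    deterministic ~``divergence`` fraction of residues substituted."""
    refs = domain_references()
    out = {}
    for domain, ref in refs.items():
        rng = _hash_rng("family-domain", family_id, domain)
        residues = list(ref)
        for i in range(len(residues)):
            if rng.random() < divergence:
                choices = _AA_ALPHABET.replace(residues[i], "")
                residues[i] = choices[rng.integers(0, len(choices))]
        out[domain] = "".join(residues)
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FamilySpec:
    """Generating parameters for one retrotransposon family."""

    family_id: str
    superfamily: str = "unclassified"  # copia | gypsy | unclassified
    ltr_length: int = 500
    internal_length: int = 2500
    domain_order: tuple[str, ...] = ()
    copy_number: int = 1
    age_distribution: object = 0.0  # years; scalar or ("uniform", lo, hi)
    solo_fraction: float = 0.0
    fragment_fraction: float = 0.0

    def __post_init__(self):
        if self.ltr_length < 50:
            raise ValueError("ltr_length must be >= 50")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.solo_fraction + self.fragment_fraction > 1 + 1e-9:
            raise ValueError("solo_fraction + fragment_fraction must be <= 1")
        if self.domain_order:
            if self.internal_length < 300:
                raise ValueError(
                    "internal_length must be >= 300 when domain_order is set"
                )
            unknown = set(self.domain_order) - set(DOMAINS)
            if unknown:
                raise ValueError(f"unknown domains: {sorted(unknown)}")
            coding = sum(3 * _DOMAIN_LENGTHS[d] for d in self.domain_order)
            if self.internal_length < coding + 60:
                raise ValueError(
                    f"internal_length {self.internal_length} too small for "
                    f"domain_order {self.domain_order} (needs >= {coding + 60})"
                )
        if self.superfamily not in ("copia", "gypsy", "unclassified"):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        object.__setattr__(self, "domain_order", tuple(self.domain_order))

    def draw_age(self, rng: np.random.Generator) -> float:
        dist = self.age_distribution
        if isinstance(dist, (int, float)):
            return float(dist)
        kind = dist[0]
        if kind == "point":
            return float(dist[1])
        if kind == "uniform":
            return float(rng.uniform(dist[1], dist[2]))
        raise ValueError(f"unknown age distribution {dist!r}")


COPIA_ORDER = ("GAG", "PR", "IN", "RT")
GYPSY_ORDER = ("GAG", "PR", "RT", "IN")


@dataclass
class PlantedElement:
    family_id: str
    insertion_site: int  # 0-based offset on the background
    age: float  # years
    tsd: str
    strand: str = "+"
    state: str = "intact"  # intact | solo_ltr | fragment
    realized_coords: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 4 <= len(self.tsd) <= 6:
            raise ValueError("TSD length must be in [4, 6]")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.state not in ("intact", "solo_ltr", "fragment"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def span(self) -> tuple[int, int]:
        return tuple(self.realized_coords["element"])


@dataclass
class SyntheticGenome:
    sequence: str
    truth: list[PlantedElement]
    params: dict

    def __post_init__(self):
        n = len(self.sequence)
        for el in self.truth:
            s, e = el.span
            if not (0 <= s <= e <= n):
                raise ValueError(f"truth interval {s, e} outside genome of {n}")

    def ltr_sequences(self, element: PlantedElement) -> tuple[str, str | None]:
        """Realized (post-mutation) 5' and 3' LTR sequences of a planted copy."""
        coords = element.realized_coords
        ltr5 = self.sequence[slice(*coords["ltr5"])] if coords.get("ltr5") else None
        ltr3 = self.sequence[slice(*coords["ltr3"])] if coords.get("ltr3") else None
        return ltr5, ltr3


@dataclass
class ReadPair:
    read1: str
    read2: str
    start1: int  # 0-based genome offset of read1 (forward strand)
    start2: int  # 0-based genome offset of the read2 segment (forward strand)


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    coverage: float
    error_rate: float
    read_length: int

    def sequences(self) -> Iterable[str]:
        for pair in self.pairs:
            yield pair.read1
            yield pair.read2


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def jc_mismatch_probability(rate: float, age: float, branches: int = 1) -> float:
    """Probability a site differs from its ancestor (branches=1) or between two
    copies diverging independently for ``age`` years (branches=2)."""
    return 0.75 * (1.0 - math.exp(-4.0 / 3.0 * rate * age * branches))


def _mutate(arr: np.ndarray, rate: float, age: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor substitutions on one branch of length rate*age."""
    p = jc_mismatch_probability(rate, age)
    out = arr.copy()
    if p <= 0 or len(arr) == 0:
        return out
    hit = np.nonzero(rng.random(len(arr)) < p)[0]
    if len(hit):
        # map base -> one of the three alternatives, uniformly
        idx = np.searchsorted(_BASES, out[hit])  # bases are sorted (A<C<G<T)
        shift = rng.integers(1, 4, len(hit))
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _encode_protein(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[res][rng.integers(0, len(_CODONS[res]))] for res in aa
    )


def _ancestral_family(spec: FamilySpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ancestral (age-0) LTR and internal region for a family."""
    rng = _hash_rng("ancestor", seed, spec.family_id)
    ltr = _random_seq_array(rng, spec.ltr_length)
    if not spec.domain_order:
        internal = _random_seq_array(rng, spec.internal_length)
        return ltr, internal
    proteins = family_domain_proteins(spec.family_id)
    coding = [_encode_protein(proteins[d], rng) for d in spec.domain_order]
    coding_len = sum(len(c) for c in coding)
    n_fillers = len(coding) + 1
    spare = spec.internal_length - coding_len
    filler_lens = [spare // n_fillers] * n_fillers
    filler_lens[-1] += spare - sum(filler_lens)
    parts: list[str] = []
    for i, chunk in enumerate(coding):
        parts.append(_to_str(_random_seq_array(rng, filler_lens[i])))
        parts.append(chunk)
    parts.append(_to_str(_random_seq_array(rng, filler_lens[-1])))
    internal = np.frombuffer("".join(parts).encode("ascii"), dtype=np.uint8).copy()
    assert len(internal) == spec.internal_length
    return ltr, internal


def _copy_states(spec: FamilySpec) -> list[str]:
    n_solo = int(round(spec.copy_number * spec.solo_fraction))
    n_frag = int(round(spec.copy_number * spec.fragment_fraction))
    while n_solo + n_frag > spec.copy_number:
        n_frag -= 1
    n_intact = spec.copy_number - n_solo - n_frag
    return ["intact"] * n_intact + ["solo_ltr"] * n_solo + ["fragment"] * n_frag


# ---------------------------------------------------------------------------
# operations


def build_genome(
    specs: Sequence[FamilySpec],
    background_length: int,
    mutation_rate: float = 1.3e-8,
    seed: int = 0,
    nesting: bool = False,
) -> SyntheticGenome:
    """Assemble an i.i.d. background with planted, aged family copies.

    Elements are inserted (not overwritten), so placed copies never overlap;
    with ``nesting`` enabled roughly one in ten intact copies is instead
    inserted into the internal region of a previously placed intact copy.
    """
    rng = np.random.default_rng(seed)
    background = _random_seq_array(rng, background_length)

    # build every copy's body first
    bodies: list[tuple[str, PlantedElement, dict]] = []
    for spec in specs:
        ltr0, internal0 = _ancestral_family(spec, seed)
        for state in _copy_states(spec):
            age = spec.draw_age(rng)
            tsd_len = int(rng.integers(4, 7))
            tsd = _to_str(_BASES[rng.integers(0, 4, tsd_len)])
            ltr_a = _to_str(_mutate(ltr0, mutation_rate, age, rng))
            parts: dict[str, tuple[int, int] | None] = {}
            if state == "solo_ltr":
                body = ltr_a
                parts = {"ltr5": (0, len(ltr_a)), "ltr3": None}
            else:
                ltr_b = _to_str(_mutate(ltr0, mutation_rate, age, rng))
                inner = _to_str(_mutate(internal0, mutation_rate, age, rng))
                body = ltr_a + inner + ltr_b
                parts = {
                    "ltr5": (0, len(ltr_a)),
                    "ltr3": (len(body) - len(ltr_b), len(body)),
                }
                if state == "fragment":
                    frac = rng.uniform(0.4, 0.9)
                    del_len = int(round(frac * len(body)))
                    del_start = int(rng.integers(0, len(body) - del_len + 1))
                    body = body[:del_start] + body[del_start + del_len :]
                    parts = {"ltr5": None, "ltr3": None}
            element = PlantedElement(
                family_id=spec.family_id,
                insertion_site=0,  # assigned at placement
                age=age,
                tsd=tsd,
                strand="+",
                state=state,
                realized_coords={},
            )
            bodies.append((body, element, parts))

    n = len(bodies)
    if n > max(background_length - 1, 0) and n > 0:
        raise PlacementError(
            f"cannot place {n} copies on a {background_length} bp background"
        )

    order = rng.permutation(n)
    sites = np.sort(rng.choice(background_length + 1, size=n, replace=False)) if n else []

    nested_idx: set[int] = set()
    if nesting and n > 1:
        intact_positions = [
            k for k in range(1, n) if bodies[order[k]][1].state == "intact"
        ]
        nested_idx = set(intact_positions[:: 10] if intact_positions else [])

    chunks: list[str] = []
    cursor = 0  # background consumed
    offset = 0  # genome length emitted
    placed: list[PlantedElement] = []
    host_pool: list[tuple[int, int]] = []  # (genome_start_of_internal, internal_len)

    for k in range(n):
        body, element, parts = bodies[order[k]]
        site = int(sites[k])
        chunks.append(_to_str(background[cursor:site]))
        offset += site - cursor
        cursor = site
        element.insertion_site = site
        tsd = element.tsd
        start = offset + len(tsd)
        insert = tsd + body + tsd
        chunks.append(insert)
        coords = {"element": (start, start + len(body))}
        for name, iv in parts.items():
            coords[name] = (start + iv[0], start + iv[1]) if iv else None
        element.realized_coords = coords
        if element.state == "intact" and element.realized_coords["ltr5"]:
            host_pool.append(
                (coords["ltr5"][1], coords["ltr3"][0] - coords["ltr5"][1])
            )
        placed.append(element)
        offset += len(insert)
    chunks.append(_to_str(background[cursor:]))
    sequence = "".join(chunks)

    # optional nesting pass: re-insert selected young copies inside hosts
    if nested_idx:
        sequence, placed = _apply_nesting(
            sequence, placed, sorted(nested_idx), order, bodies, rng
        )

    params = {
        "background_length": background_length,
        "mutation_rate": mutation_rate,
        "seed": seed,
        "nesting": nesting,
        "specs": [spec.family_id for spec in specs],
    }
    genome = SyntheticGenome(sequence=sequence, truth=placed, params=params)
    genome.params["spec_objects"] = list(specs)
    return genome


def _apply_nesting(sequence, placed, nested_positions, order, bodies, rng):
    """Move selected intact copies inside the internal region of another copy."""
    # remove the nested copies from their linear position, then re-insert
    for pos in nested_positions:
        element = placed[pos]
        if element.state != "intact" or not element.realized_coords.get("ltr5"):
            continue
        s, e = element.span
        tsd_len = len(element.tsd)
        cut_s, cut_e = s - tsd_len, e + tsd_len
        body = sequence[s:e]
        sequence = sequence[:cut_s] + sequence[cut_e:]
        removed = cut_e - cut_s
        for other in placed:
            if other is element or not other.realized_coords:
                continue
            other.realized_coords = _shift_coords(other.realized_coords, cut_s, -removed)
        # pick a host: oldest intact element other than this one
        hosts = [
            o
            for o in placed
            if o is not element and o.state == "intact" and o.realized_coords.get("ltr5")
        ]
        if not hosts:
            continue
        host = max(hosts, key=lambda o: (o.age, o.span[0]))
        int_s = host.realized_coords["ltr5"][1]
        int_e = host.realized_coords["ltr3"][0]
        if int_e - int_s < 10:
            continue
        point = int(rng.integers(int_s + 1, int_e))
        insert = element.tsd + body + element.tsd
        sequence = sequence[:point] + insert + sequence[point:]
        for other in placed:
            if other is element or not other.realized_coords:
                continue
            other.realized_coords = _shift_coords(
                other.realized_coords, point, len(insert), expand=True
            )
        b0 = point + tsd_len
        old = element.realized_coords
        shift = b0 - old["element"][0]
        element.realized_coords = {
            k: ((v[0] + shift, v[1] + shift) if v else None) for k, v in old.items()
        }
        element.insertion_site = -1  # nested: no single background offset
    return sequence, placed


def _shift_coords(coords, point, delta, expand=False):
    out = {}
    for key, iv in coords.items():
        if iv is None:
            out[key] = None
            continue
        s, e = iv
        if expand:
            s2 = s + delta if s >= point else s
            e2 = e + delta if e > point else e
        else:
            s2 = s + delta if s >= point else s
            e2 = e + delta if e >= point else e
        out[key] = (s2, e2)
    return out


def simulate_reads(
    genome: SyntheticGenome | str,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    insert_size: int = 300,
    insert_sd: float = 25.0,
) -> ReadSet:
    """Uniform-coverage paired-end reads with per-base substitution errors."""
    sequence = genome.sequence if isinstance(genome, SyntheticGenome) else genome
    length = len(sequence)
    if read_length > length:
        raise ValueError("read_length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * length / (2 * read_length)))
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    inserts = np.clip(
        np.rint(rng.normal(insert_size, insert_sd, n_pairs)).astype(np.int64),
        2 * read_length,
        length,
    )
    starts = (rng.random(n_pairs) * (length - inserts + 1)).astype(np.int64)
    pairs: list[ReadPair] = []
    for s, ins in zip(starts, inserts):
        s = int(s)
        ins = int(ins)
        frag1 = arr[s : s + read_length]
        s2 = s + ins - read_length
        frag2 = arr[s2 : s2 + read_length]
        r1 = _apply_errors(frag1, error_rate, rng)
        r2 = revcomp(_apply_errors(frag2, error_rate, rng))
        pairs.append(ReadPair(read1=r1, read2=r2, start1=s, start2=s2))
    return ReadSet(
        pairs=pairs,
        coverage=coverage,
        error_rate=error_rate,
        read_length=read_length,
    )


def _apply_errors(frag: np.ndarray, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return _to_str(frag)
    out = frag.copy()
    hit = np.nonzero(rng.random(len(out)) < error_rate)[0]
    if len(hit):
        idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, len(hit))
        out[hit] = _BASES[(idx + shift) % 4]
    return _to_str(out)


# ---------------------------------------------------------------------------
# truth ledger


_STATE_SO = {
    "intact": "LTR_retrotransposon",
    "solo_ltr": "solo_LTR",
    "fragment": "transposon_fragment",
}


def write_truth(genome: SyntheticGenome, path: str | os.PathLike, contig: str = "chr1") -> None:
    """Write the ground-truth ledger as ``<path>.gff3`` and ``<path>.tsv``."""
    gff_records = []
    rows = []
    for i, el in enumerate(genome.truth):
        s, e = el.span
        ident = f"truth{i:05d}"
        gff_records.append(
            GffRecord(
                seqid=contig,
                source="retrochrono-synth",
                type=_STATE_SO[el.state],
                start=s + 1,
                end=e,
                strand=el.strand,
                attributes={"ID": ident, "family": el.family_id, "state": el.state},
            )
        )
        for part in ("ltr5", "ltr3"):
            iv = el.realized_coords.get(part)
            if iv:
                gff_records.append(
                    GffRecord(
                        seqid=contig,
                        source="retrochrono-synth",
                        type="long_terminal_repeat",
                        start=iv[0] + 1,
                        end=iv[1],
                        strand=el.strand,
                        attributes={"Parent": ident},
                    )
                )
        row = {
            "id": ident,
            "family_id": el.family_id,
            "state": el.state,
            "age": repr(el.age),
            "tsd": el.tsd,
            "strand": el.strand,
            "insertion_site": el.insertion_site,
            "start": s,
            "end": e,
        }
        for part in ("ltr5", "ltr3"):
            iv = el.realized_coords.get(part)
            row[f"{part}_start"] = iv[0] if iv else ""
            row[f"{part}_end"] = iv[1] if iv else ""
        rows.append(row)
    path = str(path)
    ioutils.write_gff3(gff_records, path + ".gff3")
    ioutils.write_tsv(
        rows,
        path + ".tsv",
        columns=[
            "id", "family_id", "state", "age", "tsd", "strand",
            "insertion_site", "start", "end",
            "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
        ],
    )


def read_truth(path: str | os.PathLike) -> list[PlantedElement]:
    """Reconstruct the PlantedElement list from ``<path>.tsv``."""
    out = []
    for row in ioutils.read_tsv(str(path) + ".tsv"):
        coords: dict = {"element": (int(row["start"]), int(row["end"]))}
        for part in ("ltr5", "ltr3"):
            if row[f"{part}_start"]:
                coords[part] = (int(row[f"{part}_start"]), int(row[f"{part}_end"]))
            else:
                coords[part] = None
        out.append(
            PlantedElement(
                family_id=row["family_id"],
                insertion_site=int(row["insertion_site"]),
                age=float(row["age"]),
                tsd=row["tsd"],
                strand=row["strand"],
                state=row["state"],
                realized_coords=coords,
            )
        )
    return out
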