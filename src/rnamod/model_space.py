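"""Reference, modification annotation, extended alphabet, and branchable kmer space.

A reference RNA carries annotated modified positions (pseudouridine, 2'-O-methyl,
ac4C, ...).  Each annotated site is given a private single-character symbol from a
reserved pool so that every kmer containing a modified position is distinct from
every canonical kmer and from kmers of other sites: modifications are modelled
independently of each other, each with its own emission Gaussians.  The
:class:`BranchMap` expands this per-position ambiguity into, for every kmer slot
of the reference, the set of variant kmers a signal-level aligner must consider.

Coordinates are 1-based inclusive in files and reports, 0-based half-open
internally.  The RNA alphabet uses U externally; T is accepted on input and
normalized to U.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

CANONICAL_BASES = "ACGU"

#: 5'-end dead zone: the signal from the first bases of a contig is not captured
#: by standard nanopore RNA sequencing, so sites there cannot be called.
DEAD_ZONE = 15

#: Reserved single characters handed out to modified sites, in order.  Lowercase
#: letters first, then digits, then uppercase letters that are not nucleotides,
#: then a fixed ASCII punctuation extension.  Reused across contigs (uniqueness
#: is only required within a contig).
DEFAULT_MOD_CHAR_POOL = (
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
    "BDEFHIJKLMNOPQRSVWXYZ"
    "!#$%&*+-/:;<=>?@[]^_{}~"
)

#: Hard cap on ambiguous positions covered by a single kmer slot (2^4 = 16
#: variants).  The densest annotated cluster in yeast (25S 2921-2923) needs 3.
MAX_SITES_PER_SLOT = 4


class AnnotationError(ValueError):
    """Raised when an annotation row conflicts with the reference."""


@dataclass
class ModificationSite:
    """One annotated modified position on a reference contig.

    ``position`` is 1-based.  ``mod_char`` is the single character from the
    extended alphabet standing for the modified base in kmer space; it is
    assigned by :func:`assign_mod_chars`.  ``callable`` is False for sites
    inside the 5' dead zone.
    """

    contig: str
    position: int
    canonical: str
    mod_code: str
    guide: str = ""
    mod_char: str | None = None
    callable: bool = True

    @property
    def pos0(self) -> int:
        return self.position - 1

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}"


def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference into {contig: sequence}, normalized to RNA."""
    ref = {}
    for record in SeqIO.parse(str(path), "fasta"):
        ref[record.id] = normalize_rna(str(record.seq))
    if not ref:
        raise ValueError(f"no sequences in {path}")
    return ref


def load_annotation(
    path: str | Path,
    reference: dict[str, str],
    dead_zone: int = DEAD_ZONE,
) -> list[ModificationSite]:
    """Load a modification annotation table, validated against the reference.

    The TSV must carry a header with columns contig, position (1-based),
    canonical, mod_code, guide.  Sites are returned sorted by (contig,
    position); sites at positions <= ``dead_zone`` are flagged not callable.
    """
    sites: list[ModificationSite] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"contig", "position", "canonical", "mod_code"}
                if not required.issubset(header):
                    raise AnnotationError(
                        f"{path}: header must contain {sorted(required)}, got {header}"
                    )
                idx = {name: header.index(name) for name in header}
                continue
            contig = fields[idx["contig"]].strip()
            position = int(fields[idx["position"]])
            canonical = normalize_rna(fields[idx["canonical"]].strip())
            mod_code = fields[idx["mod_code"]].strip()
            guide = fields[idx["guide"]].strip() if "guide" in idx and len(fields) > idx["guide"] else ""
            if contig not in reference:
                raise AnnotationError(f"{path}:{lineno}: unknown contig {contig!r}")
            seq = reference[contig]
            if not 1 <= position <= len(seq):
                raise AnnotationError(
                    f"{path}:{lineno}: position {position} outside {contig} (length {len(seq)})"
                )
            if canonical not in CANONICAL_BASES:
                raise AnnotationError(f"{path}:{lineno}: bad canonical base {canonical!r}")
            if seq[position - 1] != canonical:
                raise AnnotationError(
                    f"{path}:{lineno}: canonical {canonical} does not match reference "
                    f"base {seq[position - 1]} at {contig}:{position}"
                )
            if (contig, position) in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate site {contig}:{position}")
            seen.add((contig, position))
            sites.append(
                ModificationSite(
                    contig=contig,
                    position=position,
                    canonical=canonical,
                    mod_code=mod_code,
                    guide=guide,
                    callable=position > dead_zone,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.position))
    return sites


@dataclass
class ModAlphabet:
    """Mapping between assigned modification characters and sites, per contig."""

    by_contig: dict[str, dict[str, int]] = field(default_factory=dict)

    def char_for(self, contig: str, position: int) -> str | None:
        for char, pos in self.by_contig.get(contig, {}).items():
            if pos == position:
                return char
        return None

    @property
    def all_chars(self) -> set[str]:
        chars: set[str] = set()
        for mapping in self.by_contig.values():
            chars.update(mapping)
        return chars


def assign_mod_chars(
    sites: Sequence[ModificationSite],
    pool: str = DEFAULT_MOD_CHAR_POOL,
) -> tuple[list[ModificationSite], ModAlphabet]:
    """Give every site a distinct modification character from the reserved pool.

    Characters are handed out deterministically in (contig, position) order,
    restarting the pool for each contig (uniqueness is per contig, so kmers of
    different sites can never collide -- each contains a character no other site
    on that contig uses).  Already-assigned sites are left untouched, which
    makes the operation idempotent.
    """
    out = sorted(sites, key=lambda s: (s.contig, s.position))
    alphabet = ModAlphabet()
    for contig, group_iter in itertools.groupby(out, key=lambda s: s.contig):
        group = list(group_iter)
        used = {s.mod_char for s in group if s.mod_char is not None}
        available = iter(c for c in pool if c not in used)
        mapping: dict[str, int] = {}
        for site in group:
            if site.mod_char is None:
                try:
                    site.mod_char = next(available)
                except StopIteration:
                    raise ValueError(
                        f"modification character pool exhausted on contig {contig} "
                        f"({len(group)} sites, pool size {len(pool)})"
                    ) from None
            mapping[site.mod_char] = site.position
        alphabet.by_contig[contig] = mapping
    return out, alphabet


@dataclass
class BranchMap:
    """Per-position allowed characters and per-slot variant kmers for one contig.

    A "slot" j (0-based) is the kmer window covering reference positions
    [j, j+k).  A slot covering b annotated callable sites has exactly 2^b
    variant kmers, one per combination of {canonical, modified} choices.
    ``slot_variants[j]`` lists ``(kmer, choices)`` with ``choices`` a tuple of
    ``(pos0, is_modified)`` for each covered site, canonical-first order.
    """

    contig: str
    seq: str
    k: int
    allowed: list[str]                      # per position: canonical char (+ mod char)
    site_pos0: list[int]                    # branchable (callable, char-assigned) sites
    mod_char_at: dict[int, str]             # pos0 -> mod char
    slot_variants: list[list[tuple[str, tuple[tuple[int, bool], ...]]]]

    @property
    def n_slots(self) -> int:
        return len(self.slot_variants)

    def slot_sites(self, j: int) -> tuple[int, ...]:
        """0-based positions of branchable sites covered by slot j."""
        return tuple(p for p in self.site_pos0 if j <= p < j + self.k)

    def canonical_kmer(self, j: int) -> str:
        return self.seq[j : j + self.k]

    def forced(self, state: str) -> "BranchMap":
        """A copy with every branchable site pinned to one character.

        ``state`` is "modified" or "canonical".  Used for supervised training
        where a read's labels are fixed dataset-wide, removing all ambiguity.
        """
        if state not in ("modified", "canonical"):
            raise ValueError(f"state must be 'modified' or 'canonical', got {state!r}")
        if state == "canonical":
            allowed = list(self.seq)
            slot_variants = [
                [(self.canonical_kmer(j), ())] for j in range(self.n_slots)
            ]
            return replace(
                self, allowed=allowed, site_pos0=[], mod_char_at={},
                slot_variants=slot_variants,
            )
        allowed = list(self.seq)
        seq_chars = list(self.seq)
        for p, c in self.mod_char_at.items():
            allowed[p] = c
            seq_chars[p] = c
        mod_seq = "".join(seq_chars)
        slot_variants = [
            [(mod_seq[j : j + self.k], ())] for j in range(self.n_slots)
        ]
        return replace(
            self, allowed=allowed, site_pos0=[], mod_char_at={},
            slot_variants=slot_variants,
        )


def build_branch_map(
    contig: str,
    seq: str,
    sites: Iterable[ModificationSite],
    k: int = 5,
    max_sites_per_slot: int = MAX_SITES_PER_SLOT,
) -> BranchMap:
    """Expand per-site ambiguity into per-slot variant kmer lists.

    Only callable sites with an assigned mod_char branch; slots covering no
    such site have a single (canonical) variant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = normalize_rna(seq)
    my_sites = sorted(
        (s for s in sites if s.contig == contig and s.callable),
        key=lambda s: s.position,
    )
    for s in my_sites:
        if s.mod_char is None:
            raise ValueError(f"site {s.key} has no assigned mod_char")
        if seq[s.pos0] != s.canonical:
            raise AnnotationError(
                f"site {s.key}: canonical {s.canonical} != reference {seq[s.pos0]}"
            )
    mod_char_at = {s.pos0: s.mod_char for s in my_sites}
    site_pos0 = sorted(mod_char_at)
    allowed = [
        seq[p] + mod_char_at[p] if p in mod_char_at else seq[p]
        for p in range(len(seq))
    ]
    n_slots = len(seq) - k + 1
    if n_slots < 1:
        raise ValueError(f"contig {contig} shorter than k={k}")
    slot_variants: list[list[tuple[str, tuple[tuple[int, bool], ...]]]] = []
    for j in range(n_slots):
        covered = [p for p in site_pos0 if j <= p < j + k]
        if len(covered) > max_sites_per_slot:
            raise ValueError(
                f"{contig}: slot {j} covers {len(covered)} annotated sites "
                f"(cap {max_sites_per_slot}); thin the annotation or raise the cap"
            )
        base = list(seq[j : j + k])
        variants = []
        for combo in itertools.product((False, True), repeat=len(covered)):
            kmer = base[:]
            for p, is_mod in zip(covered, combo):
                if is_mod:
                    kmer[p - j] = mod_char_at[p]
            variants.append(("".join(kmer), tuple(zip(covered, combo))))
        slot_variants.append(variants)
    return BranchMap(
        contig=contig,
        seq=seq,
        k=k,
        allowed=allowed,
        site_pos0=site_pos0,
        mod_char_at=mod_char_at,
        slot_variants=slot_variants,
    )


@dataclass
class KmerTable:
    """Extended-alphabet kmer -> emission Gaussian (level mean, level sd, pA)."""

    k: int
    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # kmer -> default|trained

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __getitem__(self, kmer: str) -> tuple[float, float]:
        return self.entries[kmer]

    def set(self, kmer: str, mean: float, sd: float, source: str = "default") -> None:
        if sd <= 0:
            raise ValueError(f"non-positive level sd for {kmer}: {sd}")
        if len(kmer) != self.k:
            raise ValueError(f"kmer {kmer!r} length != k={self.k}")
        self.entries[kmer] = (float(mean), float(sd))
        self.provenance[kmer] = source

    def copy(self) -> "KmerTable":
        return KmerTable(self.k, dict(self.entries), dict(self.provenance))

    def canonical_complete(self) -> bool:
        return all(
            "".join(combo) in self.entries
            for combo in itertools.product(CANONICAL_BASES, repeat=self.k)
        )


def load_kmer_table(path: str | Path) -> KmerTable:
    """Read an ONT-style level table: ``kmer level_mean level_sd [source]``.

    Whitespace-separated, one row per kmer; a header row (first field ``kmer``)
    is optional.
    """
    entries: dict[str, tuple[float, float]] = {}
    provenance: dict[str, str] = {}
    k = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0].lower() == "kmer":
                continue
            # normalize T->U only for plain nucleotide kmers; modification
            # characters (lowercase letters, digits, punctuation) are verbatim
            kmer = fields[0].replace("T", "U") if set(fields[0]) <= set("ACGTU") else fields[0]
            mean, sd = float(fields[1]), float(fields[2])
            source = fields[3] if len(fields) > 3 else "default"
            if sd <= 0:
                raise ValueError(f"{path}: non-positive sd for kmer {kmer}")
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise ValueError(f"{path}: inconsistent kmer lengths ({k} vs {len(kmer)})")
            entries[kmer] = (mean, sd)
            provenance[kmer] = source
    if k is None:
        raise ValueError(f"{path}: empty kmer table")
    return KmerTable(k=k, entries=entries, provenance=provenance)


def write_kmer_table(table: KmerTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\tlevel_sd\tsource\n")
        for kmer in sorted(table.entries):
            mean, sd = table.entries[kmer]
            source = table.provenance.get(kmer, "default")
            fh.write(f"{kmer}\t{mean:.6f}\t{sd:.6f}\t{source}\n")


def derive_branch_kmers(table: KmerTable, branch_map: BranchMap) -> KmerTable:
    """Add entries for every variant kmer of the branch map.

    New modified-kmer entries are initialized from their canonical counterpart's
    Gaussian (training then separates them); canonical kmers must already be
    present.
    """
    out = table.copy()
    for j, variants in enumerate(branch_map.slot_variants):
        canonical = branch_map.canonical_kmer(j)
        if canonical not in out:
            raise KeyError(f"canonical kmer {canonical} (slot {j}) missing from table")
        mean, sd = out[canonical]
        for kmer, choices in variants:
            if kmer not in out:
                out.set(kmer, mean, sd, source="default")
    return out


def branch_kmer_sets(branch_map: BranchMap) -> tuple[set[str], set[str]]:
    """(canonical kmers at branch slots, modified-character kmers).

    Together these are the kmers "touching a modification branch point": the
    ones supervised training re-estimates.
    """
    canonical: set[str] = set()
    modified: set[str] = set()
    for j, variants in enumerate(branch_map.slot_variants):
        if len(variants) == 1:
            continue
        for kmer, choices in variants:
            if any(m for _, m in choices):
                modified.add(kmer)
            else:
                canonical.add(kmer)
    return canonical, modified
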