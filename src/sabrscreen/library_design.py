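"""Design of pooled epitope libraries for MHC-II SABR screens.

Covers curation of published epitope lists (length trimming, modification
filtering, deduplication), combinatorial enumeration of hybrid insulin peptide
(HIP) libraries from cleavage-product halves, junction-spanning validation
epitopes, and back-translation of peptides into cloning-ready oligo pools with
restriction-site avoidance.

HIPs are non-genetically-encoded epitopes formed by post-translational fusion
of an insulin fragment (the "left" half) to a fragment of another secretory
granule protein (the "right" half); in a SABR library they are simply encoded
as the fused peptide.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from ._codon import (
    CANONICAL_AA,
    CodonSampler,
    back_translate,
    find_motif_hits,
    translate,
)

logger = logging.getLogger(__name__)

CATEGORIES = frozenset({"natural", "mimotope", "deamidated", "hip", "control"})

#: BsmBI recognition site, excised during Golden-Gate style library cloning and
#: therefore forbidden inside inserts.
BSMBI = "CGTCTC"

DEFAULT_LENGTH_BOUNDS = (9, 25)
HIP_LENGTH_BOUNDS = (12, 25)


@dataclass
class Epitope:
    """A single library epitope (peptide plus provenance annotations).

    For ``category='hip'``, ``junction_index`` is the 0-based count of residues
    contributed by the left (insulin-derived) half, i.e. the fusion point.
    """

    id: str
    peptide: str
    category: str = "natural"
    left_source: str = ""
    right_source: str = ""
    junction_index: int | None = None
    notes: str = ""

    def validate(self, length_bounds: tuple[int, int] | None = None) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")
        bad = set(self.peptide) - CANONICAL_AA
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(bad)}")
        if length_bounds is not None:
            lo, hi = length_bounds
            if not lo <= len(self.peptide) <= hi:
                raise ValueError(
                    f"{self.id}: length {len(self.peptide)} outside [{lo}, {hi}]"
                )
        if self.category == "hip":
            if self.junction_index is None or not 0 < self.junction_index < len(self.peptide):
                raise ValueError(f"{self.id}: HIP junction_index must be interior")
            if not self.left_source or not self.right_source:
                raise ValueError(f"{self.id}: HIP requires left_source and right_source")


@dataclass
class CleavageProduct:
    """A protease-cleavage fragment that can serve as one half of a HIP fusion.

    ``end='left'`` fragments provide the N-terminal half; ``end='right'``
    fragments the C-terminal half.
    """

    source_protein: str
    fragment: str
    end: str  # {"left", "right"}

    def __post_init__(self):
        if self.end not in ("left", "right"):
            raise ValueError(f"end must be 'left' or 'right', got {self.end!r}")
        if not self.fragment:
            raise ValueError("empty cleavage fragment")


@dataclass
class EpitopeLibrary:
    """An allele-restricted, ordered epitope set with optional nucleotide inserts."""

    name: str
    allele: str
    epitopes: list[Epitope]
    inserts: dict[str, str] = field(default_factory=dict)
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS

    def __len__(self) -> int:
        return len(self.epitopes)

    def __iter__(self):
        return iter(self.epitopes)

    def get(self, epitope_id: str) -> Epitope:
        for e in self.epitopes:
            if e.id == epitope_id:
                return e
        raise KeyError(epitope_id)

    @property
    def peptides(self) -> list[str]:
        return [e.peptide for e in self.epitopes]

    def back_translate_inserts(
        self, forbidden_motifs=(BSMBI,), seed: int = 0, codon_table=None
    ) -> None:
        """Populate ``inserts`` deterministically (per-epitope seed derived from
        the master seed and position, so a library edit upstream does not change
        unrelated inserts)."""
        sampler = codon_table if isinstance(codon_table, CodonSampler) else CodonSampler(codon_table)
        for i, epi in enumerate(self.epitopes):
            self.inserts[epi.id] = back_translate(
                epi.peptide, sampler, forbidden_motifs, seed=(seed * 100003 + i) % (2**31)
            )

    def validate_inserts(self, forbidden_motifs=(BSMBI,)) -> None:
        for epi in self.epitopes:
            nt = self.inserts.get(epi.id)
            if nt is None:
                raise ValueError(f"{epi.id}: missing insert")
            if translate(nt) != epi.peptide:
                raise ValueError(f"{epi.id}: insert does not translate to peptide")
            if find_motif_hits(nt, forbidden_motifs):
                raise ValueError(f"{epi.id}: insert contains forbidden motif")

    # ---- I/O -------------------------------------------------------------

    CSV_COLUMNS = ("id", "peptide", "category", "left_source", "right_source",
                   "junction_index", "notes")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.CSV_COLUMNS)
            for e in self.epitopes:
                ji = "" if e.junction_index is None else e.junction_index
                w.writerow([e.id, e.peptide, e.category, e.left_source,
                            e.right_source, ji, e.notes])

    @classmethod
    def from_csv(cls, path, name: str = "library", allele: str = "",
                 length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS) -> "EpitopeLibrary":
        epitopes = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ji = row.get("junction_index", "")
                epitopes.append(Epitope(
                    id=row["id"],
                    peptide=row["peptide"].strip().upper(),
                    category=row.get("category", "natural") or "natural",
                    left_source=row.get("left_source", "") or "",
                    right_source=row.get("right_source", "") or "",
                    junction_index=int(ji) if ji not in ("", None) else None,
                    notes=row.get("notes", "") or "",
                ))
        return cls(name=name, allele=allele, epitopes=epitopes, length_bounds=length_bounds)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.epitopes:
                fh.write(f">{e.id}\n{e.peptide}\n")


@dataclass
class OligoPool:
    """Synthesis-ready oligos: constant flanks around each epitope insert."""

    oligos: dict[str, str]
    flank5: str
    flank3: str
    forbidden_motifs: tuple[str, ...] = (BSMBI,)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for eid, oligo in self.oligos.items():
                fh.write(f">{eid}\n{oligo}\n")

    def to_csv(self, path) -> None:
        n5, n3 = len(self.flank5), len(self.flank3)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "oligo", "insert"])
            for eid, oligo in self.oligos.items():
                w.writerow([eid, oligo, oligo[n5: len(oligo) - n3]])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def curate_epitopes(
    raw,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    allowed_mods: frozenset = frozenset({"none", "deamidation", "hip"}),
) -> list[Epitope]:
    """Curate an annotated peptide list into library-ready epitopes.

    Keeps exactly the entries whose peptide length lies within ``length_bounds``
    (inclusive) and whose modification annotation is allowed, deduplicated on
    the peptide string keeping the first occurrence. Deamidation is expected to
    be represented directly in sequence (N->D / Q->E substitution), because
    SABR inserts are genetically encoded; a bare ``modification='deamidation'``
    annotation is accepted as-is.

    ``raw`` is an iterable of mappings with at least ``id`` and ``peptide``;
    optional keys: ``category``, ``modification`` (default "none"),
    ``left_source``, ``right_source``, ``junction_index``, ``notes``.

    Entries with non-canonical residues are rejected and logged, not raised.
    """
    lo, hi = length_bounds
    if lo > hi:
        raise ValueError(f"inverted length bounds ({lo}, {hi})")
    kept: list[Epitope] = []
    seen: set[str] = set()
    for rec in raw:
        rec = dict(rec)
        pep = rec["peptide"].strip().upper()
        rid = str(rec.get("id", pep))
        mod = str(rec.get("modification", "none") or "none").lower()
        if not lo <= len(pep) <= hi:
            continue
        if mod not in allowed_mods:
            continue
        if set(pep) - CANONICAL_AA:
            logger.warning("rejecting %s: non-canonical residues in %r", rid, pep)
            continue
        if pep in seen:
            logger.warning("duplicate peptide %r (record %s); keeping first occurrence", pep, rid)
            continue
        seen.add(pep)
        ji = rec.get("junction_index")
        kept.append(Epitope(
            id=rid,
            peptide=pep,
            category=str(rec.get("category", "natural") or "natural"),
            left_source=str(rec.get("left_source", "") or ""),
            right_source=str(rec.get("right_source", "") or ""),
            junction_index=int(ji) if ji not in (None, "") else None,
            notes=str(rec.get("notes", "") or ""),
        ))
    return kept


def cleavage_fragments(source_protein: str, sequence: str, cleavage_positions,
                       end: str) -> list[CleavageProduct]:
    """Derive cleavage-product halves from a protein and declared cut sites.

    ``end='left'`` returns all prefixes ending at a cut position;
    ``end='right'`` returns all suffixes starting at a cut position.
    Positions are 0-based half-open offsets into ``sequence``.
    """
    seq = sequence.strip().upper()
    out = []
    for pos in cleavage_positions:
        if not 0 < pos < len(seq) + (1 if end == "left" else 0):
            raise ValueError(f"cleavage position {pos} outside {source_protein}")
        frag = seq[:pos] if end == "left" else seq[pos:]
        if frag:
            out.append(CleavageProduct(source_protein, frag, end))
    return out


def generate_hip_library(
    left: list[CleavageProduct],
    right: list[CleavageProduct],
    length_bounds: tuple[int, int] = HIP_LENGTH_BOUNDS,
    controls: list[Epitope] | None = None,
    name: str = "hip-library",
    allele: str = "I-Ag7",
) -> EpitopeLibrary:
    """Enumerate the combinatorial HIP library: every left x right fusion whose
    total length falls in ``length_bounds``, plus positive-control epitopes.

    Each fusion is a ``category='hip'`` epitope with ``junction_index`` equal to
    the left-fragment length. Identical fused peptides are deduplicated keeping
    the first (left-major, right-minor) enumeration order.
    """
    lo, hi = length_bounds
    if lo > hi:
        raise ValueError(f"inverted length bounds ({lo}, {hi})")
    controls = list(controls or [])
    if not left:
        logger.warning("empty left fragment set: HIP library contains controls only")
    for frag in left:
        if frag.end != "left":
            raise ValueError(f"{frag.source_protein}: fragment not marked end='left'")
    for frag in right:
        if frag.end != "right":
            raise ValueError(f"{frag.source_protein}: fragment not marked end='right'")

    epitopes: list[Epitope] = []
    seen: set[str] = set()
    n = 0
    for lf in left:
        for rf in right:
            pep = lf.fragment + rf.fragment
            if not lo <= len(pep) <= hi or pep in seen:
                continue
            seen.add(pep)
            n += 1
            epitopes.append(Epitope(
                id=f"hip{n:05d}",
                peptide=pep,
                category="hip",
                left_source=lf.source_protein,
                right_source=rf.source_protein,
                junction_index=len(lf.fragment),
            ))
    for ctl in controls:
        if ctl.peptide in seen:
            logger.warning("control %s duplicates a HIP peptide; appended unchanged", ctl.id)
        epitopes.append(replace(ctl))
    return EpitopeLibrary(name=name, allele=allele, epitopes=epitopes,
                          length_bounds=(lo, hi))


def make_junction_epitope(
    hip_left_context: str,
    hip_right_context: str,
    k: int = 7,
    epitope_id: str | None = None,
    left_source: str = "",
    right_source: str = "",
) -> Epitope:
    """Build a junction-spanning validation epitope: the last ``k`` residues of
    the left context fused to the first ``k`` of the right context.

    With the default ``k=7`` the resulting 14-mer contains no 9-mer drawn wholly
    from either source protein, so an MHC-II binding register must span the
    fusion junction.
    """
    left = hip_left_context.strip().upper()
    right = hip_right_context.strip().upper()
    if len(left) < k:
        raise ValueError(f"left context shorter than k={k} ({len(left)} residues)")
    if len(right) < k:
        raise ValueError(f"right context shorter than k={k} ({len(right)} residues)")
    pep = left[-k:] + right[:k]
    return Epitope(
        id=epitope_id or f"junction_{pep}",
        peptide=pep,
        category="hip",
        left_source=left_source or "left",
        right_source=right_source or "right",
        junction_index=k,
        notes=f"junction-spanning {2 * k}-mer",
    )


class DuplicateInsertError(ValueError):
    """Raised when distinct epitopes map to identical nucleotide inserts."""

    def __init__(self, collisions):
        self.collisions = collisions
        super().__init__(f"duplicate inserts across epitopes: {collisions}")


def build_oligo_pool(
    library: EpitopeLibrary,
    flank5: str,
    flank3: str,
    forbidden_motifs=(BSMBI,),
) -> OligoPool:
    """Assemble the synthesis pool: ``flank5 + insert + flank3`` per epitope.

    Inserts must already be back-translated; they are re-validated (exact
    translation, forbidden motifs absent on both strands). Identical inserts
    from distinct epitopes raise :class:`DuplicateInsertError` listing the
    colliding ids.
    """
    library.validate_inserts(forbidden_motifs)
    by_insert: dict[str, list[str]] = {}
    for epi in library.epitopes:
        by_insert.setdefault(library.inserts[epi.id], []).append(epi.id)
    collisions = [ids for ids in by_insert.values() if len(ids) > 1]
    if collisions:
        raise DuplicateInsertError(collisions)
    oligos = {
        epi.id: flank5.upper() + library.inserts[epi.id] + flank3.upper()
        for epi in library.epitopes
    }
    return OligoPool(oligos=oligos, flank5=flank5.upper(), flank3=flank3.upper(),
                     forbidden_motifs=tuple(forbidden_motifs))
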