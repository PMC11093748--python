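"""Amplicon read processing: demultiplex, extract inserts, count epitopes.

The screen readout is a constant amplicon carrying the variable epitope insert
between fixed flanking anchors; samples are distinguished by Illumina unique
dual indexes (UDIs) carried in the read headers. Processing turns raw
FASTQ(.gz) into an epitope x sample count matrix with full read accounting:
``assigned + unmatched_insert`` per sample plus a global ``unassigned_index``
always equals the input read count.
"""

from __future__ import annotations

import csv
import gzip
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from ._codon import translate
from .library_design import EpitopeLibrary

logger = logging.getLogger(__name__)


def xopen(path, mode="rt"):
    """Open a path gzip-transparently (by .gz suffix)."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class FastqRead:
    """One sequenced read with its observed dual index pair."""

    name: str
    sequence: str
    quality: str = ""
    i7: str = ""
    i5: str = ""


def parse_fastq(path):
    """Yield :class:`FastqRead` from a FASTQ(.gz) file.

    The index pair is parsed from the Illumina-style header comment
    (``... 1:N:0:I7+I5``); reads without one get empty indexes.
    """
    with xopen(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            header = header.rstrip("\n")
            name = header[1:].split()[0]
            i7 = i5 = ""
            if " " in header:
                tag = header.rsplit(" ", 1)[1].split(":")[-1]
                if "+" in tag:
                    i7, i5 = tag.split("+", 1)
            yield FastqRead(name=name, sequence=seq.upper(), quality=qual, i7=i7, i5=i5)


@dataclass
class SampleSheet:
    """Per-sample metadata: UDI pair, screened TCR label, role and replicate."""

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "i7_index", "i5_index", "tcr_label", "role", "replicate")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        self.rows = self.rows.copy()
        self.rows["i7_index"] = self.rows["i7_index"].str.upper()
        self.rows["i5_index"] = self.rows["i5_index"].str.upper()
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        for col in ("i7_index", "i5_index"):
            if self.rows[col].str.len().nunique() > 1:
                raise ValueError(f"{col} entries differ in length")
        if self.rows.duplicated(subset=["i7_index", "i5_index"]).any():
            raise ValueError("duplicate UDI pair in sample sheet")
        bad_roles = set(self.rows["role"]) - {"sorted", "unsorted"}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype={"replicate": int}))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    def index_pairs(self) -> dict[str, tuple[str, str]]:
        return {
            r.sample_id: (r.i7_index, r.i5_index) for r in self.rows.itertuples()
        }

    def check_collisions(self, tol: int) -> None:
        """Refuse designs where a read could match two samples within `tol`.

        Two samples collide iff both their i7 and their i5 indexes are within
        2*tol of each other (a read halfway between then satisfies the
        within-tol rule for both).
        """
        pairs = list(self.index_pairs().items())
        collisions = []
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                (sa, (i7a, i5a)), (sb, (i7b, i5b)) = pairs[a], pairs[b]
                if hamming(i7a, i7b) <= 2 * tol and hamming(i5a, i5b) <= 2 * tol:
                    collisions.append((sa, sb))
        if collisions:
            raise ValueError(f"UDI collisions at tol={tol}: {collisions}")


@dataclass
class ExtractionConfig:
    """Anchored-extraction settings: constant flanks bounding the insert."""

    anchor5: str
    anchor3: str
    anchor_mismatch_tol: int = 1
    index_mismatch_tol: int = 1
    match_mode: str = "nt_exact"  # {"nt_exact", "peptide"}

    def __post_init__(self):
        if not self.anchor5 or not self.anchor3:
            raise ValueError("anchors must be non-empty")
        if self.anchor_mismatch_tol < 0 or self.index_mismatch_tol < 0:
            raise ValueError("tolerances must be >= 0")
        if self.match_mode not in ("nt_exact", "peptide"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        self.anchor5 = self.anchor5.upper()
        self.anchor3 = self.anchor3.upper()


@dataclass
class CountMatrix:
    """Epitope x sample read counts plus per-sample accounting totals.

    ``totals`` has one row per sample with columns ``assigned``,
    ``unmatched_insert`` and ``unassigned_index`` (the last is a run-level
    figure recorded on every sample's row as 0 except a dedicated
    ``__unassigned__`` row when produced by :func:`process_run`).
    """

    counts: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if s in self.totals.index:
                if int(self.counts[s].sum()) != int(self.totals.loc[s, "assigned"]):
                    raise ValueError(f"assigned total mismatch for sample {s}")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="epitope")

    @classmethod
    def from_tsv(cls, path, totals: pd.DataFrame | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="epitope")
        if totals is None:
            totals = pd.DataFrame(
                {
                    "assigned": counts.sum(axis=0).astype(int),
                    "unmatched_insert": 0,
                    "unassigned_index": 0,
                }
            )
        return cls(counts=counts, totals=totals)

    def run_report(self, path=None) -> dict:
        report = {
            "samples": {
                s: {k: int(v) for k, v in row.items()}
                for s, row in self.totals.to_dict("index").items()
            },
            "n_epitopes": int(self.counts.shape[0]),
            "grand_assigned": int(self.counts.values.sum()),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(report, fh, indent=2)
        return report


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def demultiplex(reads, sheet: SampleSheet, tol: int = 1):
    """Assign reads to samples by dual-index Hamming match.

    A read goes to the unique sample whose i7 AND i5 are each within `tol`
    mismatches of the observed indexes; ambiguous or distant reads go to the
    ``unassigned`` stream. Raises on UDI collisions at the configured `tol`.

    Returns (dict sample_id -> list of reads, list of unassigned reads).
    """
    sheet.check_collisions(tol)
    pairs = sheet.index_pairs()
    exact = {pair: sid for sid, pair in pairs.items()}
    assigned: dict[str, list] = {sid: [] for sid in pairs}
    unassigned: list = []
    for read in reads:
        obs = (read.i7, read.i5)
        sid = exact.get(obs)
        if sid is None and tol > 0:
            matches = [
                s
                for s, (i7, i5) in pairs.items()
                if len(read.i7) == len(i7)
                and len(read.i5) == len(i5)
                and hamming(read.i7, i7) <= tol
                and hamming(read.i5, i5) <= tol
            ]
            sid = matches[0] if len(matches) == 1 else None
        if sid is not None:
            assigned[sid].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


def _find_anchor(seq: str, anchor: str, tol: int, start: int = 0) -> int:
    """First position >= start where `anchor` matches with <= tol mismatches."""
    n, m = len(seq), len(anchor)
    for i in range(start, n - m + 1):
        mismatches = 0
        for a, b in zip(seq[i : i + m], anchor):
            if a != b:
                mismatches += 1
                if mismatches > tol:
                    break
        else:
            return i
    return -1


def extract_insert(read, cfg: ExtractionConfig) -> str | None:
    """Extract the insert between anchor5 and a downstream anchor3, or None.

    Mismatches up to ``cfg.anchor_mismatch_tol`` are allowed in each anchor;
    indels are not handled. Absence of either anchor (or wrong order) returns
    None — a counted outcome, not an error.
    """
    seq = read.sequence if hasattr(read, "sequence") else str(read).upper()
    i5 = _find_anchor(seq, cfg.anchor5, cfg.anchor_mismatch_tol)
    if i5 == -1:
        return None
    start = i5 + len(cfg.anchor5)
    i3 = _find_anchor(seq, cfg.anchor3, cfg.anchor_mismatch_tol, start=start)
    if i3 == -1:
        return None
    return seq[start:i3]


class _LibraryIndex:
    def __init__(self, library: EpitopeLibrary):
        self.by_insert: dict[str, str] = {}
        self.by_peptide: dict[str, str] = {}
        for epi in library.epitopes:
            self.by_peptide.setdefault(epi.peptide, epi.id)
            nt = library.inserts.get(epi.id)
            if nt is not None:
                self.by_insert.setdefault(nt.upper(), epi.id)


def assign_epitope(insert: str, library: EpitopeLibrary, mode: str = "nt_exact",
                   _index: _LibraryIndex | None = None) -> str | None:
    """Map an extracted insert to a library epitope id, or None.

    ``nt_exact`` does exact nucleotide lookup against designed inserts;
    ``peptide`` translates the in-frame insert and matches the peptide index
    (tolerating synonymous sequencing or synthesis variants). Inserts whose
    length is not a codon multiple yield None in peptide mode.
    """
    idx = _index or _LibraryIndex(library)
    insert = insert.upper()
    if mode == "nt_exact":
        return idx.by_insert.get(insert)
    if mode == "peptide":
        if len(insert) % 3 != 0 or not insert:
            return None
        try:
            pep = translate(insert)
        except Exception:
            return None
        return idx.by_peptide.get(pep)
    raise ValueError(f"unknown mode {mode!r}")


def count_sample(reads, cfg: ExtractionConfig, library: EpitopeLibrary):
    """Count epitope assignments for one sample's reads.

    Returns (pd.Series over all library epitope ids, totals dict with
    ``assigned`` and ``unmatched_insert``). Reads whose insert is missing or
    maps to no library epitope are tallied as unmatched.
    """
    idx = _LibraryIndex(library)
    counts = {epi.id: 0 for epi in library.epitopes}
    unmatched = 0
    for read in reads:
        insert = extract_insert(read, cfg)
        eid = None
        if insert is not None:
            eid = assign_epitope(insert, library, cfg.match_mode, _index=idx)
        if eid is None:
            unmatched += 1
        else:
            counts[eid] += 1
    series = pd.Series(counts, dtype=int)
    return series, {"assigned": int(series.sum()), "unmatched_insert": unmatched}


def merge_counts(columns: dict, sheet: SampleSheet | None = None,
                 unassigned_index: int = 0) -> CountMatrix:
    """Merge per-sample count columns into one matrix.

    ``columns`` maps sample_id -> (Series, totals dict). Columns are aligned on
    the union of epitope ids, filling zeros; duplicate sample ids are an error
    (enforced by the dict shape upstream and re-checked against the sheet).
    """
    if sheet is not None:
        unknown = set(columns) - set(sheet.sample_ids)
        if unknown:
            raise ValueError(f"samples not in sheet: {sorted(unknown)}")
    counts = pd.DataFrame({sid: col for sid, (col, _) in columns.items()}).fillna(0).astype(int)
    totals = pd.DataFrame(
        {
            sid: {
                "assigned": tot["assigned"],
                "unmatched_insert": tot["unmatched_insert"],
                "unassigned_index": 0,
            }
            for sid, (_, tot) in columns.items()
        }
    ).T
    if unassigned_index:
        totals.loc["__unassigned__"] = {
            "assigned": 0, "unmatched_insert": 0, "unassigned_index": int(unassigned_index),
        }
    return CountMatrix(counts=counts, totals=totals.astype(int))


def process_run(fastq_path, sheet: SampleSheet, cfg: ExtractionConfig,
                library: EpitopeLibrary) -> CountMatrix:
    """End-to-end: FASTQ -> demultiplex -> extract -> count -> merged matrix."""
    reads = parse_fastq(fastq_path)
    assigned, unassigned = demultiplex(reads, sheet, tol=cfg.index_mismatch_tol)
    columns = {sid: count_sample(rs, cfg, library) for sid, rs in assigned.items()}
    return merge_counts(columns, sheet, unassigned_index=len(unassigned))
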