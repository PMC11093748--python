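"""End-to-end screen simulation with known ground truth.

Models the physical screen abstractly: library cells each carry one epitope
construct (drawn from a log-normal abundance distribution), every cell emits a
unit-variance Gaussian reporter signal, cells whose epitope is cognate to a
TCR present in the co-incubation get an additive signal shift, the sorter
collects the top ``gate_fraction`` of cells by signal, and sequencing
multinomially down-samples each sample's cells to a fixed read depth. Raw
FASTQ with dual sample indexes and configurable substitution error rates can
be emitted for any simulated sample, so the whole read-processing and scoring
stack is testable against the simulator's truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library_design import Epitope, EpitopeLibrary
from .read_processing import CountMatrix, ExtractionConfig, SampleSheet, xopen

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_BASES = np.array(list("ACGT"))

#: Default constant amplicon flanks bounding the epitope insert. Amplicon
#: anchors are vector-derived constant sequence; at 15 nt, chance matches
#: inside inserts are negligible even under mismatch tolerance.
DEFAULT_ANCHOR5 = "ACTGGTGGCTCTGGT"
DEFAULT_ANCHOR3 = "GGTACCGAGCTCGAA"


@dataclass
class SimulationParams:
    """Screen-simulation settings.

    ``effect_size`` is the cognate signal shift in SDs of the background
    signal; ``gate_fraction`` the top percentile sorted (the screen's 1-2%
    gate); ``cognate_abundance``, when set, pins each cognate epitope's
    library abundance (cell frequency) to that value.
    """

    n_epitopes: int = 1000
    abundance_sd: float = 1.0
    gate_fraction: float = 0.02
    cognate_map: dict = field(default_factory=dict)  # tcr label -> epitope id(s)
    effect_size: float = 6.0
    reads_per_sample: int = 100_000
    n_cells: int = 1_000_000
    index_error_rate: float = 0.0
    read_error_rate: float = 0.0
    seed: int = 0
    length_bounds: tuple[int, int] = (12, 25)
    cognate_abundance: float | None = 0.0005

    def __post_init__(self):
        if self.n_epitopes < 2:
            raise ValueError("need at least 2 epitopes")
        if not 0 < self.gate_fraction <= 1:
            raise ValueError("gate_fraction must be in (0, 1]")
        for name in ("index_error_rate", "read_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_sd < 0:
            raise ValueError("abundance_sd must be >= 0")

    def cognates_of(self, tcrs) -> list[str]:
        ids: list[str] = []
        for t in tcrs:
            v = self.cognate_map.get(t, ())
            ids.extend([v] if isinstance(v, str) else list(v))
        return sorted(set(ids))

    def manifest(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cognate_map"] = {k: list(v) if not isinstance(v, str) else v
                            for k, v in self.cognate_map.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)


@dataclass
class TrueState:
    """Ground truth for one simulated co-incubation + sort."""

    cell_epitope: np.ndarray  # per-cell epitope index
    signal: np.ndarray  # per-cell reporter signal
    gate_mask: np.ndarray  # boolean gate membership
    unsorted_cell_counts: np.ndarray
    sorted_cell_counts: np.ndarray
    unsorted_reads: np.ndarray
    sorted_reads: np.ndarray
    epitope_ids: list[str]

    def pre_freq(self, epitope_id: str) -> float:
        i = self.epitope_ids.index(epitope_id)
        return self.unsorted_cell_counts[i] / self.unsorted_cell_counts.sum()

    def post_freq(self, epitope_id: str) -> float:
        i = self.epitope_ids.index(epitope_id)
        return self.sorted_cell_counts[i] / self.sorted_cell_counts.sum()


def _random_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def simulate_library(params: SimulationParams, with_inserts: bool = True,
                     allele: str = "I-Ag7"):
    """Draw a random epitope library and its log-normal abundance vector.

    Returns (EpitopeLibrary, abundance) with abundance summing to 1;
    ``abundance_sd=0`` yields exactly uniform representation. Epitope ids are
    ``epi0001`` ... and cognate ids in ``params.cognate_map`` refer to these.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.length_bounds
    seen: set[str] = set()
    epitopes: list[Epitope] = []
    while len(epitopes) < params.n_epitopes:
        pep = _random_peptide(rng, lo, hi)
        if pep in seen:
            continue
        seen.add(pep)
        epitopes.append(Epitope(id=f"epi{len(epitopes) + 1:04d}", peptide=pep))
    library = EpitopeLibrary(name="simulated", allele=allele, epitopes=epitopes,
                             length_bounds=(lo, hi))
    if with_inserts:
        library.back_translate_inserts(seed=params.seed)

    if params.abundance_sd == 0:
        abundance = np.full(params.n_epitopes, 1.0 / params.n_epitopes)
    else:
        abundance = rng.lognormal(mean=0.0, sigma=params.abundance_sd,
                                  size=params.n_epitopes)
        abundance = abundance / abundance.sum()

    if params.cognate_abundance is not None and params.cognate_map:
        ids = [e.id for e in epitopes]
        cog = [ids.index(c) for c in params.cognates_of(params.cognate_map)]
        f = params.cognate_abundance
        if f * len(cog) >= 1:
            raise ValueError("cognate_abundance too large for cognate count")
        mask = np.zeros(params.n_epitopes, dtype=bool)
        mask[cog] = True
        abundance[~mask] *= (1 - f * len(cog)) / abundance[~mask].sum()
        abundance[mask] = f
    return library, abundance


def simulate_sort(library: EpitopeLibrary, abundance: np.ndarray,
                  params: SimulationParams, tcr_set, seed: int | None = None) -> TrueState:
    """Simulate one co-incubation and top-gate sort.

    Cells are assigned epitopes proportional to abundance; background signal is
    N(0, 1); cells carrying an epitope cognate to any TCR in ``tcr_set`` get
    ``+effect_size``. The sorted sample is the top ``gate_fraction`` of cells
    by signal, the unsorted sample is all cells; both are multinomially
    down-sampled to ``reads_per_sample`` reads.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(abundance)
    ids = [e.id for e in library.epitopes]
    if n != len(ids):
        raise ValueError("abundance vector does not match library size")
    k = int(round(params.gate_fraction * params.n_cells))
    if k < 1:
        raise ValueError("sort gate smaller than one cell")

    cell_epitope = rng.choice(n, size=params.n_cells, p=abundance)
    signal = rng.standard_normal(params.n_cells)
    cognates = params.cognates_of(tcr_set)
    if cognates:
        missing = set(cognates) - set(ids)
        if missing:
            raise ValueError(f"cognate epitopes not in library: {sorted(missing)}")
        cog_idx = np.array([ids.index(c) for c in cognates])
        signal[np.isin(cell_epitope, cog_idx)] += params.effect_size

    gate_mask = np.zeros(params.n_cells, dtype=bool)
    gate_mask[np.argpartition(-signal, k - 1)[:k]] = True

    unsorted_cells = np.bincount(cell_epitope, minlength=n)
    sorted_cells = np.bincount(cell_epitope[gate_mask], minlength=n)
    unsorted_reads = rng.multinomial(params.reads_per_sample,
                                     unsorted_cells / unsorted_cells.sum())
    sorted_reads = rng.multinomial(params.reads_per_sample,
                                   sorted_cells / sorted_cells.sum())
    return TrueState(
        cell_epitope=cell_epitope, signal=signal, gate_mask=gate_mask,
        unsorted_cell_counts=unsorted_cells, sorted_cell_counts=sorted_cells,
        unsorted_reads=unsorted_reads, sorted_reads=sorted_reads, epitope_ids=ids,
    )


def enrichment_factor(pre, post, epitope) -> float:
    """Post/pre frequency ratio of one epitope.

    ``pre`` and ``post`` are abundance vectors (indexable by ``epitope`` when
    pandas Series, else ``epitope`` is a positional index); they are
    normalized to frequencies internally.
    """
    pre = pd.Series(pre) if not isinstance(pre, pd.Series) else pre
    post = pd.Series(post) if not isinstance(post, pd.Series) else post
    if epitope not in pre.index or epitope not in post.index:
        raise KeyError(f"epitope {epitope!r} absent from abundance vectors")
    f_pre = pre[epitope] / pre.sum()
    f_post = post[epitope] / post.sum()
    if f_pre <= 0:
        raise ValueError(f"epitope {epitope!r} has zero pre-sort frequency")
    return float(f_post / f_pre)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i].decode()]
        arr[i] = choices[rng.integers(len(choices))].encode()
    return arr.tobytes().decode()


def simulate_reads(state: TrueState, library: EpitopeLibrary, sheet: SampleSheet,
                   cfg: ExtractionConfig, params: SimulationParams, out_dir,
                   read_length: int | None = None, gzip_out: bool = True) -> dict:
    """Emit paired FASTQ files for the sheet's samples from a simulated sort.

    Rows with ``role='sorted'`` receive the state's sorted read counts, rows
    with ``role='unsorted'`` the unsorted counts. Each counted molecule
    becomes a read ``anchor5 + insert + anchor3`` with substitution errors at
    ``read_error_rate``; the dual indexes in the header get substitution
    errors at ``index_error_rate``. Read 2 is the reverse complement.
    Deterministic given ``params.seed``.
    """
    from pathlib import Path

    from ._codon import reverse_complement

    if not library.inserts:
        raise ValueError("library inserts must be back-translated before read simulation")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed + 7)
    inserts = [library.inserts[e.id] for e in library.epitopes]
    amplicons = [cfg.anchor5 + ins + cfg.anchor3 for ins in inserts]
    max_len = max(len(a) for a in amplicons)
    if read_length is not None and read_length < max_len:
        raise ValueError(f"read length {read_length} shorter than longest amplicon {max_len}")
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    paths: dict[str, tuple] = {}
    for row in sheet.rows.itertuples():
        counts = state.sorted_reads if row.role == "sorted" else state.unsorted_reads
        p1 = out_dir / f"{row.sample_id}_R1{suffix}"
        p2 = out_dir / f"{row.sample_id}_R2{suffix}"
        with xopen(p1, "wt") as f1, xopen(p2, "wt") as f2:
            r = 0
            for ei, c in enumerate(counts):
                for _ in range(int(c)):
                    r += 1
                    seq = _mutate(amplicons[ei], params.read_error_rate, rng)
                    i7 = _mutate(row.i7_index, params.index_error_rate, rng)
                    i5 = _mutate(row.i5_index, params.index_error_rate, rng)
                    name = f"sim:{row.sample_id}:{r}"
                    f1.write(f"@{name} 1:N:0:{i7}+{i5}\n{seq}\n+\n{'I' * len(seq)}\n")
                    rc = reverse_complement(seq)
                    f2.write(f"@{name} 2:N:0:{i7}+{i5}\n{rc}\n+\n{'I' * len(rc)}\n")
        paths[row.sample_id] = (p1, p2)
    return paths


def simulate_screen(params: SimulationParams, sorted_tcr_sets: dict,
                    n_unsorted: int = 3):
    """Simulate a complete screen straight to a count matrix.

    ``sorted_tcr_sets`` maps sorted sample ids to the TCR labels present in
    that co-incubation (one entry per sorted replicate). Unsorted replicates
    are independent multinomial draws from the library abundance. Returns
    (CountMatrix, library, abundance, dict sample -> TrueState).
    """
    library, abundance = simulate_library(params, with_inserts=False)
    rng = np.random.default_rng(params.seed + 1)
    ids = [e.id for e in library.epitopes]
    cols: dict[str, np.ndarray] = {}
    for i in range(n_unsorted):
        cols[f"unsorted_{i + 1}"] = rng.multinomial(params.reads_per_sample, abundance)
    states: dict[str, TrueState] = {}
    for j, (sample, tcrs) in enumerate(sorted_tcr_sets.items()):
        state = simulate_sort(library, abundance, params, tcrs,
                              seed=(params.seed + 1000 + 17 * j) % (2**31))
        states[sample] = state
        cols[sample] = state.sorted_reads
    counts = pd.DataFrame(cols, index=ids)
    totals = pd.DataFrame(
        {
            s: {"assigned": int(counts[s].sum()), "unmatched_insert": 0,
                "unassigned_index": 0}
            for s in counts.columns
        }
    ).T
    return CountMatrix(counts=counts, totals=totals), library, abundance, states
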