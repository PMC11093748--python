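"""Shared fixtures: a hand-annotated toy germline reference and small libraries.

The toy V segment contributes a 20-residue framework before its anchor
cysteine (index 20 of a 21-mer), the toy J contributes 5 residues after its
anchor Phe (index 0 of 'FGQGTR'), and the constant regions are 10-mers; a
reconstructed chain with an 11-residue CDR3 is therefore 46 aa with the CDR3
at offset 20, which the reconstruction tests verify by hand assembly.
"""

import pandas as pd
import pytest

from sabrscreen._codon import back_translate, translate
from sabrscreen import tcr_reconstruction as tr
from sabrscreen.library_design import Epitope, EpitopeLibrary
from sabrscreen.read_processing import ExtractionConfig, SampleSheet

# one Cys, at index 20 (the last residue) -> V framework = 20 aa
V_AA = "MKTLLVLLAVILEGDSVTQP" + "C"
# anchor F at index 0 (F-G-Q-G motif) -> J remainder after anchor = 5 aa
J_AA = "FGQGTR"
# J segment lacking any FGXG motif
BAD_J_AA = "YAQKLTRLV"
CA_AA = "EDLNKVFPPE"
CB_AA = "EDLNKAELPE"  # 'AEL' will be forced to GCTGAGCTG (BlpI site) below

CDR3B = "CASSLGGEQYF"


def _beta_constant_nt() -> str:
    nt = back_translate(CB_AA, seed=13)
    i = CB_AA.index("A") * 3
    nt = nt[:i] + "GCTGAGCTG" + nt[i + 9 :]
    assert translate(nt) == CB_AA and "GCTGAGC" in nt
    return nt


@pytest.fixture(scope="session")
def reference_fasta(tmp_path_factory):
    """Toy IMGT-style reference FASTA covering both chains plus a bad J."""
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    records = {
        "TRAV1*01": back_translate(V_AA, seed=1),
        "TRAJ1*01": back_translate(J_AA, seed=2),
        "TRAC*01": back_translate(CA_AA, seed=3),
        "TRBV2*01": back_translate(V_AA, seed=4),
        "TRBJ2*01": back_translate(J_AA, seed=5),
        "TRBC*01": _beta_constant_nt(),
        "TRBJ9*01": back_translate(BAD_J_AA, seed=6),
    }
    with open(path, "w") as fh:
        for name, nt in records.items():
            fh.write(f">{name}\n{nt}\n")
    return path


@pytest.fixture(scope="session")
def reference(reference_fasta):
    return tr.load_allele_reference(reference_fasta)


@pytest.fixture()
def toy_library():
    """3-epitope library with deterministic inserts."""
    epitopes = [
        Epitope(id="e1", peptide="SHLVEALYLVCGERG"),
        Epitope(id="e2", peptide="LQTLALWSRMDQLA", category="hip",
                left_source="InsC", right_source="ChgA", junction_index=6),
        Epitope(id="e3", peptide="AVRPLWVRMEHHHHH", category="mimotope"),
    ]
    lib = EpitopeLibrary(name="toy", allele="I-Ag7", epitopes=epitopes,
                         length_bounds=(9, 25))
    lib.back_translate_inserts(seed=42)
    return lib


@pytest.fixture()
def sample_sheet():
    return SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2", "u1"],
        "i7_index": ["ACGTACGT", "TTTTCCCC", "GGGGAAAA"],
        "i5_index": ["CAGTCAGT", "AAAACCCC", "TTTTGGGG"],
        "tcr_label": ["TCR1", "TCR1", ""],
        "role": ["sorted", "sorted", "unsorted"],
        "replicate": [1, 2, 1],
    }))


@pytest.fixture()
def extraction_config():
    return ExtractionConfig(anchor5="ACTGGTGGCTCTGGT", anchor3="GGTACCGAGCTCGAA")
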