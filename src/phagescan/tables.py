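"""Loaders for the packaged SPP1 reference tables.

Three plain-text fixtures ship with the package: the 13 Rho-independent
terminator sequences with their printed stem-loop free energies, the 80
annotated heavy-strand ORFs (RBS pattern, spacing, coordinates, length,
mass), and the SPP1 vs *B. subtilis* codon-usage table.  They are the
desk-scale ground truth the analysis modules are validated against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("phagescan") / "data"


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_terminator_table() -> pd.DataFrame:
    """13 terminator sequences: sequence, start_nt, end_nt, dg_printed."""
    return _read("table2_terminators.tsv")


def load_orf_table() -> pd.DataFrame:
    """80 heavy-strand ORF records.

    Columns: orf, rbs_mrna, spacing, start_codon, start_nt, stop_codon,
    stop_nt, length_aa, mm_kda, essential, tmm, note.  ``rbs_mrna`` is the
    printed pattern with mismatches in lowercase; missing RBS (ORFs 2 and
    16) is NaN with note ``no_rbs``; ORF 42.2 carries note ``weak_rbs``.
    """
    df = _read("table3_orfs.tsv", dtype={"orf": str})
    df["note"] = df["note"].fillna("")
    return df


def load_codon_usage_table() -> pd.DataFrame:
    """Per-codon counts and within-family fractions for SPP1 and B. subtilis."""
    return _read("table4_codon_usage.tsv")


def load_residue_masses() -> dict[str, float]:
    df = _read("residue_masses.tsv")
    return dict(zip(df["residue"], df["mass"]))


def load_stack_energies() -> dict[tuple[str, str], float]:
    """Nearest-neighbor stack table, closed under strand-flip symmetry."""
    df = _read("rna_stack_energies.tsv")

    def flip(pair: str) -> str:
        a, b = pair.split(":")
        return f"{b}:{a}"

    table: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        p1, p2, dg = row["pair1"], row["pair2"], float(row["dg"])
        table[(p1, p2)] = dg
        table.setdefault((flip(p2), flip(p1)), dg)
    return table


def load_loop_penalties() -> dict[int, float]:
    df = _read("hairpin_loop_penalties.tsv")
    return {int(r["loop_len"]): float(r["dg"]) for _, r in df.iterrows()}
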