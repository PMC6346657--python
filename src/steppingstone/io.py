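"""Readers and writers: FASTA + deme-map TSV, result tables, exports.

The on-disk dataset format is a plain FASTA of haploid sequences plus a
tab-separated map with columns ``sample_id``, ``deme`` and
``lattice_position``; the classic migrate-n infile can also be written for
cross-checking against that program.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hky import BASE_INDEX
from .simulate import LabeledAlignment


def write_fasta(aln: LabeledAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_deme_map(aln: LabeledAlignment, path) -> None:
    pd.DataFrame(
        {
            "sample_id": aln.ids,
            "deme": [aln.deme_names[d] for d in aln.deme_of_sample],
            "lattice_position": aln.lattice_position[aln.deme_of_sample],
        }
    ).to_csv(path, sep="\t", index=False)


def write_dataset(aln: LabeledAlignment, fasta_path, tsv_path) -> None:
    write_fasta(aln, fasta_path)
    write_deme_map(aln, tsv_path)


def read_alignment(fasta_path, deme_tsv_path) -> LabeledAlignment:
    """Load a FASTA + deme-map pair into a :class:`LabeledAlignment`.

    Sequence case is collapsed; characters outside ACGT are rejected
    (simulated and curated haplotype data are expected to be clean, and
    silently recoding ambiguity codes would bias the haplotype-identity
    statistics).
    """
    table = pd.read_csv(deme_tsv_path, sep="\t")
    deme_of = dict(zip(table["sample_id"].astype(str), table["deme"].astype(str)))
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    missing = [r.id for r in records if r.id not in deme_of]
    if missing:
        raise ValueError(f"samples missing from the deme map: {missing}")
    unused = set(deme_of) - {r.id for r in records}
    if unused:
        raise ValueError(f"deme map lists samples absent from the FASTA: {sorted(unused)}")
    deme_names = sorted(set(deme_of.values()))
    if "lattice_position" in table.columns:
        pos_of = dict(zip(table["deme"].astype(str), table["lattice_position"]))
        order = sorted(deme_names, key=lambda d: float(pos_of[d]))
        deme_names = order
        positions = np.array([float(pos_of[d]) for d in deme_names])
    else:
        positions = np.arange(len(deme_names), dtype=float)
    deme_index = {d: i for i, d in enumerate(deme_names)}
    length = len(records[0].seq)
    codes = np.zeros((len(records), length), dtype=np.uint8)
    demes = np.zeros(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise ValueError("all sequences must have equal length")
        try:
            codes[i] = [BASE_INDEX[c] for c in seq]
        except KeyError as err:
            raise ValueError(f"non-ACGT character in {rec.id}: {err}") from None
        demes[i] = deme_index[deme_of[rec.id]]
    return LabeledAlignment(
        codes=codes, ids=[r.id for r in records], deme_of_sample=demes,
        lattice_position=positions, deme_names=deme_names,
    )


def write_pairwise_matrix(mat, deme_names, path) -> None:
    values = mat.values if hasattr(mat, "values") and not isinstance(mat, pd.DataFrame) else mat
    pd.DataFrame(values, index=deme_names, columns=deme_names).to_csv(path, sep="\t")


def write_migrate_infile(aln: LabeledAlignment, path, title: str = "steppingstone") -> None:
    """Classic migrate-n sequence infile: header, locus lengths, per-deme blocks."""
    with open(path, "w") as fh:
        fh.write(f"{aln.n_demes} 1 {title}\n")
        fh.write(f"{aln.locus_length}\n")
        for d in range(aln.n_demes):
            idx = aln.samples_in_deme(d)
            fh.write(f"{len(idx)} {aln.deme_names[d]}\n")
            for i in idx:
                fh.write(f"{aln.ids[i][:10]:<10}{aln.sequences[i]}\n")


def write_newick(state, path=None) -> str:
    """Newick string of a sampler genealogy, with migration events as
    square-bracket comments ``[&migrations={t:a->b,...}]`` on each branch."""
    def annot(node: int) -> str:
        times = state.path_times[node]
        if len(times) == 0:
            return ""
        src = [int(state.node_deme[node])] + [int(d) for d in state.path_demes[node][:-1]]
        parts = [
            f"{t + state.time[node]:.6g}:{a}->{int(b)}"
            for t, a, b in zip(times, src, state.path_demes[node])
        ]
        return "[&migrations={" + ",".join(parts) + "}]"

    def rec(node: int) -> str:
        if node < state.n_tips:
            label = f"t{node}_d{int(state.node_deme[node])}"
        else:
            kids = ",".join(rec(int(c)) for c in state.children[node])
            label = f"({kids})"
        p = int(state.parent[node])
        if p == -1:
            return label
        return f"{label}:{state.time[p] - state.time[node]:.8g}{annot(node)}"

    text = rec(state.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
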