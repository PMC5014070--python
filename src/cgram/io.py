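"""Readers and writers for the package's text formats.

Every writer stamps a ``# cgram v<version>`` provenance comment; readers
skip ``#`` lines, so all formats round-trip.  Sequences live in plain-text
``.seq`` files (one label per line, optional second column of durations, or
a single whitespace/comma separated line — auto-detected).  Dictionaries,
arcs and dendrograms serialize to JSON and TSV; Markov matrices to a
delimited table with a state-label header row.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .compression import Arc, CompressionResult, DendrogramNode, Rule
from .core_sequences import WarpedSequence
from .motif_stats import ComparisonResult, MotifTable
from .null_models import MarkovModel
from .synthetic_data import Cohort, CohortSpec, PlantedMotif

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_dictionary_json",
    "write_dictionary_json",
    "write_dictionary_text",
    "write_arcs_tsv",
    "write_arcs_json",
    "dendrogram_to_dict",
    "write_motif_table",
    "read_motif_table",
    "write_comparison",
    "read_markov",
    "write_markov",
    "read_cohort_spec",
    "write_cohort",
    "read_cohort",
]


def _version() -> str:
    try:
        return version("cgram")
    except PackageNotFoundError:  # running from a source tree
        return "0.1.0"


def _provenance() -> str:
    return f"# cgram v{_version()}"


def _atomic_write(path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------- sequences


def read_sequence(path) -> WarpedSequence:
    """Auto-detecting sequence reader.

    Accepts one label per line, ``label<ws>duration`` per line, or a single
    whitespace/comma separated line of labels.  Raises with the file name
    and line number on malformed content.
    """
    path = Path(path)
    labels: list[int] = []
    durations: list[float] = []
    have_durations = False
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            data_lines.append((lineno, stripped))
    if len(data_lines) == 1 and len(re.split(r"[,\s]+", data_lines[0][1])) > 2:
        lineno, line = data_lines[0]
        for tok in re.split(r"[,\s]+", line):
            try:
                labels.append(int(tok))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: not an integer label: {tok!r}"
                ) from exc
    else:
        for lineno, line in data_lines:
            parts = re.split(r"[,\s]+", line)
            try:
                labels.append(int(parts[0]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: not an integer label: {parts[0]!r}"
                ) from exc
            if len(parts) > 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'label [duration]', got {line!r}"
                )
            if len(parts) == 2:
                have_durations = True
                try:
                    durations.append(float(parts[1]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: not a numeric duration: {parts[1]!r}"
                    ) from exc
            elif have_durations:
                raise ValueError(f"{path}:{lineno}: missing duration column")
    alphabet = max(max(labels, default=1), 90)
    return WarpedSequence(
        labels,
        durations if have_durations else None,
        alphabet_size=alphabet,
        strict=False,
    )


def write_sequence(path, seq: WarpedSequence) -> None:
    """Two-column form: one ``label duration`` pair per line."""
    lines = [_provenance()]
    for lab, dur in zip(seq.labels, seq.durations):
        lines.append(f"{lab}\t{dur:g}")
    _atomic_write(path, "\n".join(lines) + "\n")


# --------------------------------------------------------------- dictionary


def _result_to_dict(result: CompressionResult) -> dict:
    return {
        "format": "cgram-dictionary",
        "version": _version(),
        "alphabet_size": result.alphabet_size,
        "l": result.l,
        "compressibility": result.compressibility,
        "compressed": list(result.compressed),
        "rules": [
            {
                "symbol": r.symbol,
                "body": list(r.body),
                "W": r.W,
                "N": r.N,
                "savings": r.savings,
                "starts": list(r.starts),
                "orig_starts": list(r.orig_starts),
            }
            for r in result.rules
        ],
    }


def write_dictionary_json(path, result: CompressionResult) -> None:
    _atomic_write(path, json.dumps(_result_to_dict(result), indent=1) + "\n")


def read_dictionary_json(path) -> CompressionResult:
    with open(path) as fh:
        data = json.load(fh)
    rules = tuple(
        Rule(
            symbol=r["symbol"],
            body=tuple(r["body"]),
            N=r["N"],
            savings=r["savings"],
            starts=tuple(r["starts"]),
            orig_starts=tuple(r["orig_starts"]),
        )
        for r in data["rules"]
    )
    return CompressionResult(
        compressed=tuple(data["compressed"]),
        rules=rules,
        l=data["l"],
        compressibility=data["compressibility"],
        alphabet_size=data["alphabet_size"],
    )


def write_dictionary_text(path, result: CompressionResult) -> None:
    """Human-readable dictionary: one rule per record."""
    lines = [
        _provenance(),
        f"# l={result.l} compressed={len(result.compressed)} "
        f"compressibility={result.compressibility:.6g}",
        "symbol\tbody\tW\tN\tsavings\tstarts",
    ]
    for r in result.rules:
        lines.append(
            f"{r.symbol}\t{'-'.join(map(str, r.body))}\t{r.W}\t{r.N}"
            f"\t{r.savings}\t{','.join(map(str, r.starts))}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


# ------------------------------------------------------- arcs / dendrograms


def write_arcs_tsv(path, arcs: Sequence[Arc]) -> None:
    lines = [_provenance(), "symbol\tstart_a\tstart_b\twidth"]
    for a in arcs:
        lines.append(f"{a.symbol}\t{a.start_a}\t{a.start_b}\t{a.width}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_arcs_json(path, arcs: Sequence[Arc]) -> None:
    data = {
        "format": "cgram-arcs",
        "version": _version(),
        "arcs": [
            {
                "symbol": a.symbol,
                "start_a": a.start_a,
                "start_b": a.start_b,
                "width": a.width,
            }
            for a in arcs
        ],
    }
    _atomic_write(path, json.dumps(data, indent=1) + "\n")


def dendrogram_to_dict(node: DendrogramNode) -> dict:
    return {
        "symbol": node.symbol,
        "count": node.count,
        "children": [dendrogram_to_dict(c) for c in node.children],
    }


# ------------------------------------------------------------- motif tables


def write_motif_table(path, table: MotifTable) -> None:
    """TSV: motif (hyphen-joined labels), origin, then one frequency column
    per individual; condition labels in a second header comment."""
    lines = [
        _provenance(),
        "# conditions\t" + "\t".join(table.conditions),
        "motif\torigin\t"
        + "\t".join(f"ind{j}" for j in range(table.n_individuals)),
    ]
    for i, motif in enumerate(table.motifs):
        freqs = "\t".join(f"{v:.10g}" for v in table.frequencies[i])
        lines.append(f"{'-'.join(map(str, motif))}\t{table.origin[i]}\t{freqs}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_motif_table(path) -> MotifTable:
    path = Path(path)
    conditions: tuple[str, ...] | None = None
    motifs: list[tuple[int, ...]] = []
    origin: list[str] = []
    freq_rows: list[list[float]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("# conditions\t"):
                conditions = tuple(stripped.split("\t")[1:])
                continue
            if not stripped or stripped.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            parts = stripped.split("\t")
            motifs.append(tuple(int(x) for x in parts[0].split("-")))
            origin.append(parts[1])
            freq_rows.append([float(x) for x in parts[2:]])
    if conditions is None:
        raise ValueError(f"{path}: missing '# conditions' header")
    return MotifTable(
        motifs=tuple(motifs),
        origin=tuple(origin),
        frequencies=np.asarray(freq_rows, dtype=float),
        conditions=conditions,
    )


def write_comparison(path, result: ComparisonResult) -> None:
    df = result.table.copy()
    df["motif"] = df["motif"].map(lambda m: "-".join(map(str, m)))
    df["pair"] = df["pair"].map(lambda p: f"{p[0]}|{p[1]}")
    text = _provenance() + f"\n# fdr_level\t{result.fdr_level}\n"
    text += df.to_csv(sep="\t", index=False)
    _atomic_write(path, text)


# ----------------------------------------------------------- markov matrices


def write_markov(path, model: MarkovModel) -> None:
    """Delimited transition matrix with a state-label header row; the
    initial distribution rides along as a comment."""
    lines = [
        _provenance(),
        "# initial\t"
        + "\t".join(f"{p:.10g}" for p in model.initial_distribution),
        "\t".join(str(s) for s in model.states),
    ]
    for row in model.transition_matrix:
        lines.append("\t".join(f"{p:.10g}" for p in row))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_markov(path) -> MarkovModel:
    path = Path(path)
    initial = None
    rows: list[list[float]] = []
    states: tuple[int, ...] | None = None
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("# initial\t"):
                initial = [float(x) for x in stripped.split("\t")[1:]]
                continue
            if not stripped or stripped.startswith("#"):
                continue
            if states is None:
                states = tuple(int(x) for x in stripped.split("\t"))
                continue
            rows.append([float(x) for x in stripped.split("\t")])
    if states is None or initial is None:
        raise ValueError(f"{path}: malformed Markov matrix file")
    return MarkovModel(states, np.asarray(rows), np.asarray(initial))


# ----------------------------------------------------------------- cohorts


def read_cohort_spec(path) -> CohortSpec:
    """CohortSpec from a YAML config.

    Keys: conditions, n_per_condition, sequence_length, alphabet_size,
    seed, planted_motifs (list of {motif: [...], rates: {cond: rate}}),
    base_model ("uniform" or a path to a Markov matrix file).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    base_model = data.get("base_model", "uniform")
    if isinstance(base_model, str) and base_model != "uniform":
        base_model = read_markov(Path(path).parent / base_model)
    motifs = tuple(
        PlantedMotif(motif=tuple(pm["motif"]), rates=dict(pm["rates"]))
        for pm in data.get("planted_motifs", [])
    )
    return CohortSpec(
        conditions=tuple(data["conditions"]),
        n_per_condition=int(data["n_per_condition"]),
        sequence_length=int(data["sequence_length"]),
        alphabet_size=int(data.get("alphabet_size", 90)),
        base_model=base_model,
        planted_motifs=motifs,
        seed=int(data.get("seed", 0)),
    )


def write_cohort(outdir, cohort: Cohort) -> None:
    """One ``indNNN.seq`` per individual plus ``conditions.tsv`` and the
    ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, (seq, cond) in enumerate(zip(cohort.sequences, cohort.conditions)):
        name = f"ind{j:03d}.seq"
        write_sequence(outdir / name, seq)
        rows.append(f"{name}\t{cond}")
    _atomic_write(
        outdir / "conditions.tsv",
        _provenance() + "\nfile\tcondition\n" + "\n".join(rows) + "\n",
    )
    _atomic_write(
        outdir / "ground_truth.json",
        json.dumps(
            {
                "format": "cgram-ground-truth",
                "version": _version(),
                "planted_motifs": [
                    {"motif": list(g["motif"]), "rates": g["rates"]}
                    for g in cohort.ground_truth()
                ],
            },
            indent=1,
        )
        + "\n",
    )


def read_cohort(indir) -> tuple[list[WarpedSequence], list[str]]:
    """Sequences + condition labels from a cohort directory."""
    indir = Path(indir)
    sequences: list[WarpedSequence] = []
    conditions: list[str] = []
    with open(indir / "conditions.tsv") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#") or stripped == "file\tcondition":
                continue
            name, cond = stripped.split("\t")
            sequences.append(read_sequence(indir / name))
            conditions.append(cond)
    return sequences, conditions
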