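"""Shared readers and writers for the pipeline's text formats.

Conventions: TSV is the universal tabular dialect (tab-separated, ``#``
comment lines); time series are CSV with explicit unit columns; motif and
sequence coordinates are 1-based; every writer prepends a provenance header
(package version, seed when one applies).  All writers are deterministic for
identical inputs.
"""

from __future__ import annotations

import io as _stdio
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .eetscreen import ProteinRecord
from .markers import AnnotatedTree, ModuleDefinition, ScoreSet, TipEvidence
from .physiology import TimeSeries

import numpy as np


def provenance_header(seed: int | None = None, **extra) -> str:
    parts = [f"misokit v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in sorted(extra.items()))
    return "# " + " ".join(parts)


# ---------------------------------------------------------------------------
# Trees


def read_newick(path) -> AnnotatedTree:
    """Read a newick tree with plain-number internal-node supports."""
    return AnnotatedTree.from_file(path)


def write_newick(tree: AnnotatedTree, path, seed: int | None = None) -> None:
    # newick has no '#' comments; provenance goes in a bracketed comment
    with open(path, "w") as fh:
        fh.write("[" + provenance_header(seed).lstrip("# ") + "]\n")
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; ids to first whitespace, sequences uppercased."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                   for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Evidence, localization, score and module tables (TSV)


def read_evidence(path) -> dict[str, TipEvidence]:
    """TSV: tip_id, status, neighbourhood_labels (';'-joined), trait_labels."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        out[row["tip_id"]] = TipEvidence(
            status=row["status"],
            neighbourhood_labels=frozenset(x for x in row.get("neighbourhood_labels", "").split(";") if x),
            trait_labels=frozenset(x for x in row.get("trait_labels", "").split(";") if x),
        )
    return out


def write_evidence(evidence: Mapping[str, TipEvidence], path,
                   seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("tip_id\tstatus\tneighbourhood_labels\ttrait_labels\n")
        for tip in sorted(evidence):
            ev = evidence[tip]
            fh.write(f"{tip}\t{ev.status}\t"
                     f"{';'.join(sorted(ev.neighbourhood_labels))}\t"
                     f"{';'.join(sorted(ev.trait_labels))}\n")


def read_localizations(path) -> dict[str, str]:
    """TSV: protein_id, localization."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df["protein_id"], df["localization"]))


def write_localizations(locs: Mapping[str, str], path,
                        seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("protein_id\tlocalization\n")
        for pid in sorted(locs):
            fh.write(f"{pid}\t{locs[pid]}\n")


def read_scoreset(path) -> ScoreSet:
    """Labelled score TSV: sequence_id, model_id, bit_score, label.

    Accepts hmmsearch-tabular-like column order; the label column holds
    ``positive``/``negative``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return ScoreSet(ids=tuple(df["sequence_id"].astype(str)),
                    scores=df["bit_score"].to_numpy(dtype=float),
                    labels=(df["label"].astype(str) == "positive").to_numpy())


def write_scoreset(scores: ScoreSet, path, model_id: str = "model",
                   seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("sequence_id\tmodel_id\tbit_score\tlabel\n")
        for sid, score, lab in zip(scores.ids, scores.scores, scores.labels):
            fh.write(f"{sid}\t{model_id}\t{score:.6g}\t"
                     f"{'positive' if lab else 'negative'}\n")


def read_gene_scores(path) -> dict[str, dict[str, float]]:
    """Unlabelled hit TSV (sequence_id, model_id, bit_score) -> nested dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sequence_id"]), {})[str(row["model_id"])] = \
            float(row["bit_score"])
    return out


def read_modules(path) -> list[ModuleDefinition]:
    """Module TSV: module_id, diagnostic ids (';'-joined), logic expression."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [ModuleDefinition(module_id=row["module_id"],
                             expression=row["expression"],
                             diagnostic=frozenset(row["diagnostic"].split(";")))
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Time series (CSV: condition, replicate, time, unit, analyte, value)

_TS_COLUMNS = ["condition", "replicate", "time", "unit", "analyte", "value"]


def read_timeseries(path) -> list[TimeSeries]:
    """Read a time-series CSV into one TimeSeries per (condition, analyte,
    replicate) group; rows may arrive in any order."""
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in _TS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"time-series file lacks columns: {', '.join(missing)}")
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = int(coerced.index[coerced.isna()][0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric {col!r} at row {bad}")
        df[col] = coerced
    series = []
    for (cond, analyte, rep), grp in df.groupby(
            ["condition", "analyte", "replicate"], sort=True):
        grp = grp.sort_values("time")
        units = grp["unit"].unique()
        series.append(TimeSeries(time=grp["time"].to_numpy(float),
                                 value=grp["value"].to_numpy(float),
                                 unit=str(units[0]), analyte=str(analyte),
                                 condition=str(cond), replicate=str(rep)))
    return series


def write_timeseries(series: Iterable[TimeSeries], path,
                     seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write(",".join(_TS_COLUMNS) + "\n")
        for ts in series:
            for t, v in zip(ts.time, ts.value):
                fh.write(f"{ts.condition},{ts.replicate},{t:.10g},"
                         f"{ts.unit},{ts.analyte},{v:.10g}\n")


# ---------------------------------------------------------------------------
# ROI ion-count tables


def read_roi_counts(path) -> pd.DataFrame:
    """ROI TSV: roi_id, day, c12c12, c12c13 (+ optional c12n14, p31, s32)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"roi_id": str, "day": str})
    for col in ("c12c12", "c12c13"):
        if col not in df.columns:
            raise ValueError(f"ROI table lacks column {col!r}")
        df[col] = df[col].astype(int)
    return df


def write_roi_counts(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write any result DataFrame as provenance-headed TSV."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_profile(profile, path, seed: int | None = None) -> None:
    """Write an energy profile as TSV (pH, dGr_kJ_mol, dGr_per_e_kJ)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, reaction=profile.reaction_label,
                                   scenario=profile.scenario) + "\n")
        fh.write("pH\tdGr_kJ_mol\tdGr_per_e_kJ\n")
        for p, g, ge in zip(profile.pH_grid, profile.dgr, profile.dgr_per_electron):
            fh.write(f"{p:.6g}\t{g:.6f}\t{ge:.6f}\n")
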