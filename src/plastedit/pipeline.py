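"""Pipeline orchestration, packaged fixtures, and summary reports.

Two first-class paths exist: *pipeline mode* runs pileup → call → annotate →
summarize → expression on a reference + alignments (typically synthetic),
and *fixture mode* computes the same summaries from the packaged published
site and expression tables, which is the desk-reproducible surface of the
study this package models.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .calling import EditingSite, call_sites, substitution_spectrum, write_sites_tsv
from .codons import (
    CodonChange,
    annotate_site,
    classify_fixture_row,
    summarize_by_group,
    summarize_spectrum,
)
from .expression import ExpressionRecord, expression_table, write_expression_tsv
from .genome import Plastome, read_plastome
from .pileup import pileup_from_sam, pileup_from_truth

__all__ = [
    "AnalysisReport",
    "FIXTURE_ROW_COUNTS",
    "load_fixture",
    "fixture_summaries",
    "run_pipeline",
]

#: Packaged-fixture schema guards: expected row counts.
FIXTURE_ROW_COUNTS = {"table2": 91, "table3": 80}

_TABLE2_COLUMNS = [
    "gene",
    "site",
    "position_printed",
    "aa_index",
    "nt_index_printed",
    "codon_before",
    "codon_after",
    "aa_before_printed",
    "aa_after_printed",
    "coverage",
    "count_ref",
    "count_alt",
    "printed_pct_ref",
    "printed_pct_alt",
    "synonymous_flag_printed",
]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table (``"table2"`` or ``"table3"``).

    Site-table rows gain derived columns: ``recomputed_pct_alt`` (edited reads /
    printed coverage, in percent), ``conversion`` (gene-strand content from
    the printed codons), and for coding rows ``klass_from_codons`` with an
    ``inconsistent`` flag for rows whose printed codons differ at more than
    one position.
    """
    if name not in FIXTURE_ROW_COUNTS:
        raise ValueError(f"unknown fixture {name!r}; expected one of "
                         f"{sorted(FIXTURE_ROW_COUNTS)}")
    path = resources.files("plastedit.data") / f"{name}_fixture.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"aa_index": str})
    n_expected = FIXTURE_ROW_COUNTS[name]
    if len(df) != n_expected:
        raise ValueError(f"{name} fixture has {len(df)} rows, expected {n_expected}")
    if name == "table3":
        for col in ("gene", "length_bp", "rpkm"):
            if col not in df.columns:
                raise ValueError(f"table3 fixture missing column {col!r}")
        return df
    missing = [c for c in _TABLE2_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table2 fixture missing columns {missing}")
    for i, row in df.iterrows():
        if row["count_ref"] < 0 or row["count_alt"] < 0 or row["coverage"] <= 0:
            raise ValueError(f"table2 row {i} ({row['gene']}): bad counts")

    df["recomputed_pct_alt"] = 100.0 * df["count_alt"] / df["coverage"]
    df["is_rrna"] = df["gene"].str.startswith("rrn")

    conversions, klasses, inconsistent = [], [], []
    for _, row in df.iterrows():
        cb, ca = row["codon_before"], row["codon_after"]
        if row["is_rrna"]:
            conversions.append(f"{cb}-to-{ca}")
            klasses.append(None)
            inconsistent.append(False)
            continue
        diff = [k for k in range(3) if cb[k] != ca[k]]
        k = diff[0] if diff else 0
        conversions.append(f"{cb[k]}-to-{ca[k]}")
        klass, bad = classify_fixture_row(cb, ca)
        klasses.append(klass)
        inconsistent.append(bad)
    df["conversion"] = conversions
    df["klass_from_codons"] = klasses
    df["inconsistent"] = inconsistent
    return df


def fixture_summaries(table2: pd.DataFrame | None = None) -> dict:
    """Published-table summaries: group tallies, spectra, substitution classes.

    Counts are defined on the fixture exactly as printed (91 rows).  The
    amino-acid spectrum uses the table's printed amino-acid letters; the
    synonymous/nonsynonymous split uses classification from the printed
    codons (reported alongside the count of printed synonymous asterisks,
    which differs for rows where the two disagree).
    """
    df = load_fixture("table2") if table2 is None else table2
    coding = df[~df["is_rrna"]]
    aa_pairs = list(zip(coding["aa_before_printed"], coding["aa_after_printed"]))
    aa_spectrum = summarize_spectrum(aa_pairs)
    return {
        "n_rows": len(df),
        "group_counts": summarize_by_group(df["gene"]),
        "gene_counts": df["gene"].value_counts().to_dict(),
        "rrna_sites": int(df["is_rrna"].sum()),
        "conversion_spectrum": substitution_spectrum(df["conversion"]),
        "aa_spectrum_printed": aa_spectrum,
        "synonymous_from_codons": int((coding["klass_from_codons"] == "synonymous").sum()),
        "synonymous_printed_flags": int(coding["synonymous_flag_printed"].sum()),
        "inconsistent_rows": int(coding["inconsistent"].sum()),
    }


@dataclass
class AnalysisReport:
    """End-to-end pipeline output plus run metadata."""

    sites: list[EditingSite]
    changes: list[CodonChange]
    group_tally: dict[str, int]
    conversion_spectrum: dict[str, int]
    aa_spectrum: dict
    synonymous: int
    nonsynonymous: int
    expression: list[ExpressionRecord]
    metadata: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = [
            "plastedit analysis summary",
            "==========================",
            f"editing sites called: {len(self.sites)}",
            f"  coding: {sum(1 for s in self.sites if s.region == 'coding')}"
            f"  rRNA: {sum(1 for s in self.sites if s.region == 'rRNA')}"
            f"  tRNA: {sum(1 for s in self.sites if s.region == 'tRNA')}"
            f"  IGS: {sum(1 for s in self.sites if s.region == 'IGS')}",
            f"synonymous / nonsynonymous: {self.synonymous} / {self.nonsynonymous}",
            "conversion spectrum: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.conversion_spectrum.items())),
            "sites per gene group:",
        ]
        for group, n in sorted(self.group_tally.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {group}: {n}")
        if self.expression:
            top = self.expression[:3]
            lines.append(
                "top expressed genes: "
                + ", ".join(f"{r.gene} (RPKM {r.rpkm:.1f})" for r in top)
            )
        lines.append("run metadata: " + ", ".join(f"{k}={v}" for k, v in self.metadata.items()))
        return "\n".join(lines) + "\n"


def run_pipeline(
    ref_fasta: str | Path,
    gff3: str | Path,
    sam_or_truth,
    threshold: float = 0.05,
    min_coverage: int = 10,
    allowed_conversions="default",
    max_mismatches: int | None = 2,
    outdir: str | Path | None = None,
    seed: int | None = None,
    log=sys.stderr,
) -> AnalysisReport:
    """Run pileup → call → annotate → summarize → expression.

    ``sam_or_truth`` is either a SAM path (mismatch-filtered) or an iterable
    of truth alignments (unfiltered).  With ``outdir`` set, the TSV tables
    and a plain-text summary are written there; every number in the summary
    is recomputable from the TSVs.
    """
    from .calling import DEFAULT_CONVERSIONS

    if allowed_conversions == "default":
        allowed_conversions = DEFAULT_CONVERSIONS

    def stage(msg: str, t0: float) -> None:
        if log is not None:
            print(f"[plastedit] {msg} ({time.perf_counter() - t0:.2f}s)", file=log)

    t0 = time.perf_counter()
    plastome = read_plastome(ref_fasta, gff3)
    stage(f"loaded {plastome.seq_id} ({len(plastome)} bp, {len(plastome.genes)} genes)", t0)

    t0 = time.perf_counter()
    if isinstance(sam_or_truth, (str, Path)):
        pileups = pileup_from_sam(sam_or_truth, plastome, max_mismatches=max_mismatches)
    else:
        pileups = pileup_from_truth(sam_or_truth, plastome)
    stage(f"pileup over {len(pileups)} covered positions", t0)

    t0 = time.perf_counter()
    sites = call_sites(
        pileups,
        plastome,
        threshold=threshold,
        min_coverage=min_coverage,
        allowed_conversions=allowed_conversions,
    )
    changes = [annotate_site(s, plastome) for s in sites if s.region == "coding"]
    aa_spectrum = summarize_spectrum(changes)
    synonymous = sum(1 for c in changes if c.klass == "synonymous")
    tally = summarize_by_group(s for s in sites if s.gene is not None)
    stage(f"called {len(sites)} sites", t0)

    t0 = time.perf_counter()
    expression = expression_table(sam_or_truth, plastome)
    stage("expression table", t0)

    report = AnalysisReport(
        sites=sites,
        changes=changes,
        group_tally=tally,
        conversion_spectrum=substitution_spectrum(sites),
        aa_spectrum=aa_spectrum,
        synonymous=synonymous,
        nonsynonymous=len(changes) - synonymous,
        expression=expression,
        metadata={
            "threshold": threshold,
            "min_coverage": min_coverage,
            "seed": seed,
            "version": __version__,
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sites_tsv(sites, outdir / "sites.tsv")
        write_expression_tsv(expression, outdir / "expression.tsv")
        _write_changes_tsv(changes, outdir / "codon_changes.tsv")
        (outdir / "summary.txt").write_text(report.summary_text())
    return report


def _write_changes_tsv(changes: Iterable[CodonChange], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\taa_index\tnt_index\tcodon_pos\tcodon_before\tcodon_after\t"
            "aa_before\taa_after\tklass\tdisplay\n"
        )
        for c in changes:
            fh.write(
                f"{c.gene}\t{c.aa_index}\t{c.nt_index}\t{c.codon_pos}\t"
                f"{c.codon_before}\t{c.codon_after}\t{c.aa_before}\t{c.aa_after}\t"
                f"{c.klass}\t{c.display}\n"
            )
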