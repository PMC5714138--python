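"""FASTA input, fixture generation, TSV output and histogram reports.

All outputs are TSV (scientific notation, 6 significant digits) with a
header comment embedding the parameter-set fingerprint and the 1-based
transcript coordinate convention, so any file can be traced back to the
exact configuration that produced it.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .accuracy import AccuracyProfile

logger = logging.getLogger(__name__)


def read_fasta(path: str) -> list[SeqRecord]:
    """Read and validate DNA records (coding/sense strand).

    Sequences are uppercased and must contain only A, C, G, T; the first
    offending position is reported. An empty file is an error.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base not in "ACGT":
                raise ValueError(
                    f"record {rec.id!r}: non-DNA character {base!r} at position {pos}")
        out.append(SeqRecord(Seq(seq), id=rec.id, description=rec.description))
    return out


def generate_random_template(length: int, gc_fraction: float = 0.5,
                             seed: int = 0, record_id: str = "random_template"
                             ) -> SeqRecord:
    """Reproducible random DNA template with a target GC content."""
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return SeqRecord(Seq(seq), id=record_id,
                     description=f"length={length} gc={gc_fraction} seed={seed}")


def _header(fingerprint: str, extra: str = "") -> str:
    lines = ["# txfidelity output; positions are 1-based transcript (coding-strand) coordinates",
             f"# params_fingerprint={fingerprint}"]
    if extra:
        lines.append(f"# {extra}")
    return "\n".join(lines) + "\n"


def write_profile_tsv(profile: AccuracyProfile, path: str) -> None:
    """Per-position profile TSV (round-trips exactly via ``read_profile_tsv``)."""
    with open(path, "w") as fh:
        fh.write(_header(profile.fingerprint, f"sequence_id={profile.sequence_id}"))
        profile.per_position.to_csv(fh, sep="\t", float_format="%.6e")


def read_profile_tsv(path: str) -> pd.DataFrame:
    with open(path) as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(_io.StringIO(body), sep="\t", index_col="position")


def write_summary_tsv(summary: pd.DataFrame, fingerprint: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(fingerprint))
        summary.to_csv(fh, sep="\t", float_format="%.6e")


def histogram_report(profile: AccuracyProfile, weighted: bool = True,
                     n_bins: int = 30, column: str | None = None) -> pd.DataFrame:
    """Log10-binned error-probability histogram, one series per cognate base.

    Mirrors the grouped presentation of per-position error probabilities:
    each series counts template positions whose cognate substrate is X and
    whose error probability falls in the bin. ``weighted`` selects the
    concentration-weighted Err; otherwise the unweighted variant.
    """
    if profile.per_position.empty:
        raise ValueError("empty profile")
    col = column or ("Err" if weighted else "Err_unweighted")
    err = profile.per_position[col]
    lo = np.floor(np.log10(err.min()) * 2) / 2
    hi = np.ceil(np.log10(err.max()) * 2) / 2
    if hi <= lo:
        hi = lo + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    out = {}
    for base, grp in profile.per_position.groupby("cognate_base"):
        counts, _ = np.histogram(np.log10(grp[col]), bins=edges)
        out[base] = counts
    df = pd.DataFrame(out, index=pd.IntervalIndex.from_breaks(np.round(edges, 6),
                                                              name="log10_err_bin"))
    return df.fillna(0).astype(int)


def plot_histogram(hist: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a histogram table to PNG (headless backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = np.array([iv.mid for iv in hist.index])
    fig, ax = plt.subplots(figsize=(7, 4))
    width = (centers[1] - centers[0]) / (len(hist.columns) + 1) if len(centers) > 1 else 0.1
    for k, base in enumerate(hist.columns):
        ax.bar(centers + k * width, hist[base], width=width, label=f"cognate {base}")
    ax.set_xlabel("log10 error probability")
    ax.set_ylabel("positions")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
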