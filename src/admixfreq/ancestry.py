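"""Local-ancestry calls (MSP-style interval files) and confusion matrices.

Local-ancestry callers such as RFMix2 and Gnomix emit an ``msp.tsv``: a
two-header-line TSV whose first line maps ancestry labels to integer codes
and whose data rows are genomic windows, one ancestry code per haplotype
column.  Intervals are half-open ``[spos, epos)`` on the 1-based physical
axis; a site at ``pos == epos`` of one window belongs to the next.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default four-way continental code book (matches the simulator default)
DEFAULT_CODE_BOOK = {0: "AFR", 1: "EUR", 2: "EAS", 3: "IND"}


class MspFormatError(ValueError):
    """Raised for malformed MSP content."""


@dataclass
class AncestryCalls:
    """Per-haplotype local-ancestry codes along the genome.

    Parameters
    ----------
    code_book
        Mapping of integer code -> ancestry label.
    samples
        Ordered sample ids; haplotype columns are ``sample.0, sample.1``.
    intervals
        Per chromosome: ``(spos, epos, codes)`` where ``spos``/``epos`` are
        int arrays of half-open window bounds (non-overlapping, sorted) and
        ``codes`` is an ``(n_windows, 2N)`` int8 matrix.
    """

    code_book: dict[int, str]
    samples: list[str]
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (spos, epos, codes) in self.intervals.items():
            if not (epos > spos).all():
                raise MspFormatError(f"{chrom}: empty or inverted interval")
            if (spos[1:] < epos[:-1]).any():
                raise MspFormatError(f"{chrom}: overlapping intervals")
            if codes.shape != (len(spos), 2 * len(self.samples)):
                raise MspFormatError(f"{chrom}: code matrix shape mismatch")

    @property
    def labels(self) -> list[str]:
        return [self.code_book[k] for k in sorted(self.code_book)]

    def code_for(self, label: str) -> int:
        for code, lab in self.code_book.items():
            if lab == label:
                return code
        raise KeyError(f"unknown ancestry label {label!r}; have {self.labels}")

    def ancestry_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Resolve each (haplotype, position) to an ancestry code.

        Returns a ``(2N, n_positions)`` int8 matrix; positions not covered
        by any interval resolve to ``-1``.
        """
        positions = np.asarray(positions)
        if chrom not in self.intervals:
            return np.full((2 * len(self.samples), len(positions)), -1, np.int8)
        spos, epos, codes = self.intervals[chrom]
        idx = np.searchsorted(spos, positions, side="right") - 1
        inside = (idx >= 0) & (positions < epos[np.clip(idx, 0, None)])
        out = np.full((2 * len(self.samples), len(positions)), -1, np.int8)
        if inside.any():
            out[:, inside] = codes[idx[inside]].T
        return out

    def genome_fractions(self) -> pd.DataFrame:
        """Per-sample genome fraction of each ancestry (haplotypes averaged).

        Fractions are tract-length weighted over covered intervals and sum
        to 1 per sample over the ancestry labels.
        """
        K = len(self.code_book)
        codes_sorted = sorted(self.code_book)
        lengths = np.zeros((2 * len(self.samples), K))
        for spos, epos, codes in self.intervals.values():
            w = (epos - spos).astype(float)
            for j, code in enumerate(codes_sorted):
                lengths[:, j] += ((codes == code).astype(float) * w[:, None]).sum(0)
        total = lengths.sum(axis=1, keepdims=True)
        if (total == 0).any():
            raise ValueError("haplotype with no covered intervals")
        frac = lengths / total
        per_ind = (frac[0::2] + frac[1::2]) / 2.0
        return pd.DataFrame(
            per_ind, index=self.samples,
            columns=[self.code_book[c] for c in codes_sorted],
        )


def read_msp(path: str) -> AncestryCalls:
    """Parse an RFMix2/Gnomix-style ``msp.tsv`` file."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#Subpopulation order/codes:"):
            raise MspFormatError(f"{path}: missing subpopulation code header")
        code_book: dict[int, str] = {}
        for tok in first.split(":", 1)[1].strip().replace("\t", " ").split():
            label, _, code = tok.partition("=")
            if not code:
                raise MspFormatError(f"{path}: bad code token {tok!r}")
            code_book[int(code)] = label
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        body = pd.read_csv(io.StringIO(fh.read()), sep="\t", names=header)
    fixed = ["chm", "spos", "epos", "sgpos", "egpos", "n snps"]
    if header[: len(fixed)] != fixed:
        raise MspFormatError(f"{path}: unexpected column header {header[:6]}")
    hap_cols = header[len(fixed):]
    samples: list[str] = []
    for col in hap_cols:
        sample, _, hap = col.rpartition(".")
        if hap not in ("0", "1"):
            raise MspFormatError(f"{path}: haplotype column {col!r} not sample.0/1")
        if hap == "0":
            samples.append(sample)
        elif sample != samples[-1]:
            raise MspFormatError(f"{path}: haplotype columns out of pair order")
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in body.groupby("chm", sort=False):
        grp = grp.sort_values("spos")
        intervals[str(chrom)] = (
            grp["spos"].to_numpy(np.int64),
            grp["epos"].to_numpy(np.int64),
            grp[hap_cols].to_numpy(np.int8),
        )
    return AncestryCalls(code_book=code_book, samples=samples, intervals=intervals)


def write_msp(calls: AncestryCalls, path: str, bp_per_morgan: float = 1e8) -> None:
    """Write :class:`AncestryCalls` in the MSP TSV dialect read by `read_msp`."""
    with open(path, "w") as fh:
        codes = "\t".join(
            f"{calls.code_book[c]}={c}" for c in sorted(calls.code_book)
        )
        fh.write(f"#Subpopulation order/codes: {codes}\n")
        hap_cols = [f"{s}.{h}" for s in calls.samples for h in (0, 1)]
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(hap_cols) + "\n")
        cm_per_bp = 100.0 / bp_per_morgan
        for chrom, (spos, epos, codes_m) in calls.intervals.items():
            for i in range(len(spos)):
                sg = (spos[i] - 1) * cm_per_bp
                eg = (epos[i] - 1) * cm_per_bp
                fh.write(
                    f"{chrom}\t{spos[i]}\t{epos[i]}\t{sg:.5f}\t{eg:.5f}\t0\t"
                    + "\t".join(map(str, codes_m[i])) + "\n"
                )
    logger.info("wrote MSP with %d samples to %s", len(calls.samples), path)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic K x K matrix: ``matrix[true, assigned]``.

    Rows are the true local ancestry, columns the caller's assignment; each
    row sums to 1.  Row/column order follows ``labels``.
    """

    matrix: np.ndarray
    labels: tuple[str, ...] = field(default=tuple(DEFAULT_CODE_BOOK[k] for k in sorted(DEFAULT_CODE_BOOK)))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("confusion matrix must be K x K matching labels")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("confusion matrix entries must be in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")

    @classmethod
    def identity(cls, labels: tuple[str, ...] | None = None) -> "ConfusionMatrix":
        labels = labels or tuple(DEFAULT_CODE_BOOK[k] for k in sorted(DEFAULT_CODE_BOOK))
        return cls(np.eye(len(labels)), tuple(labels))

    @classmethod
    def read_tsv(cls, path: str) -> "ConfusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(df.to_numpy(float), tuple(df.columns))

    def write_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels)) \
            .to_csv(path, sep="\t")
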