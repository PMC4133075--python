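"""SNP marker handling: loading, coding, quality control, relatedness.

Markers are biallelic and coded -1 / 0 / +1 for the two homozygotes and the
heterozygote; missing calls stay missing (NaN) at load time and are only
zeroed when a matrix is encoded for genomic prediction.  Quality control
drops monomorphic markers, markers with minor allele frequency below a
threshold, and markers with too much missing data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_ALLOWED = {-1.0, 0.0, 1.0}


@dataclass
class MarkerMatrix:
    """Genotype x marker matrix of coded SNP values.

    ``data`` is a float DataFrame (rows = genotypes, columns = markers) with
    entries in {-1, 0, 1} or NaN for missing calls.
    """

    data: pd.DataFrame

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, [-1.0, 0.0, 1.0]))
        if bad.any():
            raise ValueError(f"marker matrix contains codes outside {{-1,0,1}}: "
                             f"{np.unique(vals[bad])[:5]}")

    @property
    def genotypes(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def maf(self) -> pd.Series:
        """Per-marker minor allele frequency.

        The heterozygote (code 0) counts one copy of each allele; missing
        entries are excluded from the denominator.
        """
        vals = self.data.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            # allele 'A' copies: +1 -> 2, 0 -> 1, -1 -> 0  <=>  code + 1
            copies = np.where(obs, vals + 1.0, 0.0).sum(axis=0)
            freq = np.where(n_obs > 0, copies / (2.0 * np.maximum(n_obs, 1)), np.nan)
        maf = np.minimum(freq, 1.0 - freq)
        return pd.Series(maf, index=self.data.columns, name="maf")

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=0).rename("missing_fraction")


@dataclass
class QCReport:
    """Counts of markers dropped by each quality-control rule."""

    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_high_missing: int
    n_surviving: int

    def __post_init__(self):
        dropped = self.n_monomorphic + self.n_low_maf + self.n_high_missing
        assert dropped + self.n_surviving == self.n_input

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def load_markers(path, fmt: str = "csv") -> MarkerMatrix:
    """Read a coded marker matrix from CSV or a biallelic VCF.

    CSV: genotypes in the first column, one column per marker, missing as
    empty cells.  VCF: diploid GT fields map 0/0 -> -1, 0/1 -> 0, 1/1 -> +1,
    ./. -> missing; multi-allelic records are rejected.
    """
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        try:
            return MarkerMatrix(df.astype(float))
        except ValueError as exc:
            raise ValueError(f"could not parse marker CSV {path}: {exc}") from exc
    if fmt == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown marker format: {fmt!r}")


def _load_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) > 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; only biallelic sites are supported"
            )
        codes = np.full(len(samples), np.nan)
        for s, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            codes[s] = float(a + b - 1)
        rows.append(codes)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    data = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    return MarkerMatrix(data)


def write_markers(m: MarkerMatrix, path) -> None:
    """Write the coded matrix as CSV with missing entries as empty cells."""
    out = m.data.copy()
    # keep integer look for coded values
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index_label="genotype")


def qc_filter(
    m: MarkerMatrix, maf_min: float = 0.01, max_missing: float = 0.10
) -> tuple[MarkerMatrix, QCReport]:
    """Drop monomorphic, low-MAF and high-missingness markers.

    A marker is monomorphic if it shows at most one distinct non-missing
    code; low-MAF if MAF < ``maf_min`` (strict, so a marker at exactly the
    threshold is kept); high-missing if its missing fraction exceeds
    ``max_missing`` (strict ">", so exactly 10% missing is kept).  The three
    rules are counted in that order for the report; the surviving set does
    not depend on the order.
    """
    vals = m.data
    n_distinct = vals.nunique(axis=0, dropna=True)
    mono = n_distinct <= 1
    low_maf = (m.maf() < maf_min) & ~mono
    high_miss = (m.missing_fraction() > max_missing) & ~mono & ~low_maf
    keep = ~(mono | low_maf | high_miss)
    report = QCReport(
        n_input=vals.shape[1],
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low_maf.sum()),
        n_high_missing=int(high_miss.sum()),
        n_surviving=int(keep.sum()),
    )
    if report.n_surviving == 0:
        raise ValueError(f"all markers dropped by QC: {report.to_json()}")
    return MarkerMatrix(vals.loc[:, keep]), report


def encode_for_gp(m: MarkerMatrix) -> pd.DataFrame:
    """Numeric matrix for genomic prediction: missing -> 0, no centering.

    The regression carries an intercept, so the raw {-1, 0, 1} codes are
    used as-is; missing calls and technical failures take the heterozygote
    code 0.
    """
    return m.data.fillna(0.0)


def realized_relationship(Z) -> pd.DataFrame:
    """Marker-based realized relationship matrix Z Z' / p.

    Uses the same scaling as the genomic-prediction kernel (Gamma = ZZ'/p)
    for internal consistency.  Symmetric and positive semi-definite by
    construction.
    """
    if isinstance(Z, MarkerMatrix):
        Z = encode_for_gp(Z)
    idx = Z.index if isinstance(Z, pd.DataFrame) else None
    A = np.asarray(Z, dtype=float)
    if A.ndim != 2 or A.shape[1] == 0:
        raise ValueError("relationship matrix requires at least one marker")
    G = A @ A.T / A.shape[1]
    G = (G + G.T) / 2
    if idx is not None:
        return pd.DataFrame(G, index=idx, columns=idx)
    return pd.DataFrame(G)


def relationship_heatmap(G: pd.DataFrame, path) -> None:
    """Save a relatedness heat-map (higher value = stronger relationship)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(G, float), cmap="viridis")
    fig.colorbar(im, ax=ax, label="realized relationship")
    ax.set_xlabel("genotype")
    ax.set_ylabel("genotype")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
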