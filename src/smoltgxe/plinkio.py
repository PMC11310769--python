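"""SNP panel container and PLINK-style file codecs (PED/MAP, BED/BIM/FAM).

Genotypes are held as an individuals x markers matrix of A1-allele dosage
(count of the BIM/MAP first allele) in {0, 1, 2}, with ``MISSING`` (-9) as
the missing sentinel. Binary bed files follow the SNP-major v1.00 layout
(magic bytes 0x6c 0x1b 0x01, two bits per call).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-9)

#: two-bit bed codes -> A1 dosage (00 hom A1, 01 missing, 10 het, 11 hom A2)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

MARKER_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


class FormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


@dataclass
class SnpPanel:
    """Genotype matrix plus marker map and individual ids.

    ``geno[i, j]`` is the dosage of allele ``markers.a1[j]`` carried by
    individual ``ids[i]``.
    """

    ids: list[str]
    markers: pd.DataFrame
    geno: np.ndarray
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.markers = self.markers.reset_index(drop=True)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.ids), len(self.markers)):
            raise FormatError(
                f"genotype matrix {self.geno.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        ok = np.isin(self.geno, [0, 1, 2, MISSING])
        if not ok.all():
            bad = np.unique(self.geno[~ok])
            raise FormatError(f"invalid dosage values {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.geno == MISSING

    def allele_freq(self) -> np.ndarray:
        """Observed A1 frequency per marker over non-missing calls (NaN if none)."""
        g = np.where(self.geno == MISSING, np.nan, self.geno.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def subset(self, individuals=None, marker_idx=None) -> "SnpPanel":
        ids, geno = self.ids, self.geno
        if individuals is not None:
            pos = {ind: i for i, ind in enumerate(ids)}
            rows = [pos[i] for i in individuals]
            ids = list(individuals)
            geno = geno[rows]
        markers = self.markers
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            markers = markers.iloc[marker_idx]
            geno = geno[:, marker_idx]
        sex = {i: self.sex[i] for i in ids if i in self.sex}
        return SnpPanel(ids, markers.reset_index(drop=True), geno.copy(), sex)

    # ------------------------------------------------------------------ I/O

    def write(self, prefix: str, fmt: str = "bed") -> None:
        if fmt == "bed":
            write_bed(self, prefix)
        elif fmt == "ped":
            write_ped(self, prefix)
        else:
            raise FormatError(f"unknown format {fmt!r}")


def read_panel(prefix: str, fmt: str | None = None) -> SnpPanel:
    """Read a panel from ``prefix``.{ped,map} or ``prefix``.{bed,bim,fam}.

    Autodetects the format when ``fmt`` is None.
    """
    if fmt is None:
        fmt = "bed" if os.path.exists(prefix + ".bed") else "ped"
    if fmt == "bed":
        return read_bed(prefix)
    if fmt == "ped":
        return read_ped(prefix)
    raise FormatError(f"unknown format {fmt!r}")


def _read_map(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, snp, _cm, pos = parts
                a1, a2 = "A", "B"
            elif len(parts) == 6:  # bim
                chrom, snp, _cm, pos, a1, a2 = parts
            else:
                raise FormatError(f"{path}:{lineno}: expected 4 or 6 fields")
            rows.append((snp, chrom, int(pos), a1, a2))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def _write_map(markers: pd.DataFrame, path: str, bim: bool) -> None:
    with open(path, "w") as fh:
        for r in markers.itertuples():
            if bim:
                fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")
            else:
                fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\n")


def read_ped(prefix: str) -> SnpPanel:
    markers = _read_map(prefix + ".map")
    m = len(markers)
    a1 = markers["a1"].to_numpy()
    a2 = markers["a2"].to_numpy()
    ids: list[str] = []
    sex: dict[str, str] = {}
    rows = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            iid = parts[1]
            ids.append(iid)
            sex[iid] = parts[4]
            al = np.array(parts[6:], dtype=object).reshape(m, 2)
            dosage = np.full(m, MISSING, dtype=np.int8)
            miss = (al[:, 0] == "0") | (al[:, 1] == "0")
            known = ~miss
            d = (al[known, 0] == a1[known]).astype(np.int8) + (
                al[known, 1] == a1[known]
            ).astype(np.int8)
            valid = np.isin(al[known], np.stack([a1[known], a2[known]], axis=1)).all(
                axis=1
            )
            if not valid.all():
                j = np.flatnonzero(known)[~valid][0]
                raise FormatError(
                    f"{prefix}.ped:{lineno}: unknown allele code "
                    f"{al[j].tolist()} at marker {markers['snp'].iloc[j]}"
                )
            dosage[known] = d
            rows.append(dosage)
    geno = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    return SnpPanel(ids, markers, geno, sex)


def write_ped(panel: SnpPanel, prefix: str) -> None:
    _write_map(panel.markers, prefix + ".map", bim=False)
    a1 = panel.markers["a1"].to_numpy()
    a2 = panel.markers["a2"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, iid in enumerate(panel.ids):
            g = panel.geno[i]
            pairs = np.empty((len(g), 2), dtype=object)
            pairs[g == 2] = np.stack([a1[g == 2], a1[g == 2]], axis=1)
            pairs[g == 1] = np.stack([a1[g == 1], a2[g == 1]], axis=1)
            pairs[g == 0] = np.stack([a2[g == 0], a2[g == 0]], axis=1)
            pairs[g == MISSING] = ["0", "0"]
            sx = panel.sex.get(iid, "0")
            fh.write(
                f"FAM {iid} 0 0 {sx} -9 " + " ".join(pairs.ravel().tolist()) + "\n"
            )


def read_bed(prefix: str) -> SnpPanel:
    markers = _read_map(prefix + ".bim")
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    ids = fam["iid"].tolist()
    sex = dict(zip(ids, fam["sex"]))
    n, m = len(ids), len(markers)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic bytes {magic.hex()}")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bpm = (n + 3) // 4
    if raw.size != bpm * m:
        raise FormatError(
            f"{prefix}.bed: {raw.size} data bytes, expected {bpm * m} "
            f"for {n} individuals x {m} SNPs"
        )
    raw = raw.reshape(m, bpm)
    # unpack 2-bit codes, individual-fastest within byte (LSB first)
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    geno = _BED_DECODE[codes[:, :n]].T.copy()
    return SnpPanel(ids, markers, geno, sex)


def write_bed(panel: SnpPanel, prefix: str) -> None:
    _write_map(panel.markers, prefix + ".bim", bim=True)
    with open(prefix + ".fam", "w") as fh:
        for iid in panel.ids:
            fh.write(f"FAM {iid} 0 0 {panel.sex.get(iid, '0')} -9\n")
    n, m = panel.n_individuals, panel.n_markers
    bpm = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)  # dosage int8 (viewed as uint8) -> code
    for dval, code in _BED_ENCODE.items():
        lut[np.uint8(np.int8(dval))] = code
    codes = lut[panel.geno.T.astype(np.int8).view(np.uint8)]  # m x n
    padded = np.zeros((m, bpm * 4), dtype=np.uint8)  # pad bits zeroed (bed format)
    padded[:, :n] = codes
    out = np.zeros((m, bpm), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())
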