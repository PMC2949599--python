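"""Readers and writers: site lists (plain/BED/GFF3), TSV outputs, manifests.

Positions are 0-based internally.  BED starts are already 0-based
half-open and are used as-is; GFF3 records are 1-based and converted,
taking the strand-aware transcription start (``start`` on ``+``,
``end`` on ``-``).
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .positional import PositionalScoreTable
from .solenoid import SiteSequence
from .spectrum import PeakSet, SolenoidalSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "read_sites",
    "write_spectrum",
    "read_spectrum",
    "write_positional",
    "write_peaks",
    "write_manifest",
]


def _finish(
    records: list[tuple[str, int]],
    fmt: str,
    length: int | None,
    pragma_lengths: dict[str, int],
    chrom: str | None,
) -> SiteSequence:
    if not records:
        raise ValueError("no site positions found in input")
    names = sorted({name for name, _ in records})
    if chrom is not None:
        records = [r for r in records if r[0] == chrom]
        if not records:
            raise ValueError(f"no records for sequence {chrom!r} (found {names})")
    elif len(names) > 1:
        raise ValueError(
            "input contains several sequences; pass chrom to select one of "
            f"{names} (the congruence is only meaningful within one support)"
        )
    positions = np.array([pos for _, pos in records], dtype=np.int64)
    name = records[0][0]
    if length is None:
        length = pragma_lengths.get(name)
    if length is None:
        length = int(positions.max()) + 1
        logger.warning(
            "support length not given; using max(position)+1 = %d", length
        )
    return SiteSequence(length, positions)


def read_sites(
    path,
    fmt: str = "positions",
    length: int | None = None,
    chrom: str | None = None,
    feature_type: str = "gene",
) -> SiteSequence:
    """Read a site list from plain positions, BED intervals or GFF3 records.

    Parameters
    ----------
    fmt:
        ``"positions"`` (one integer per line), ``"bed"`` (0-based start
        per interval) or ``"gff3"`` (strand-aware transcription start of
        every record whose type matches ``feature_type``; pass
        ``feature_type=None`` to keep all records).
    length:
        Support length override; otherwise taken from a GFF3
        ``##sequence-region`` pragma, else ``max(position) + 1`` with a
        warning.
    chrom:
        Sequence name to select when the file covers several.
    """
    path = Path(path)
    records: list[tuple[str, int]] = []
    pragma_lengths: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if fmt == "gff3" and line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    pragma_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            try:
                if fmt == "positions":
                    records.append(("", int(line.split()[0])))
                elif fmt == "bed":
                    fields = line.split("\t")
                    records.append((fields[0], int(fields[1])))
                elif fmt == "gff3":
                    fields = line.split("\t")
                    if len(fields) < 7:
                        raise ValueError("GFF3 record has fewer than 7 fields")
                    if feature_type is not None and fields[2] != feature_type:
                        continue
                    start, end, strand = int(fields[3]), int(fields[4]), fields[6]
                    tss = start - 1 if strand != "-" else end - 1
                    records.append((fields[0], tss))
                else:
                    raise ValueError(f"unknown format {fmt!r}")
            except (ValueError, IndexError) as exc:
                if "unknown format" in str(exc):
                    raise
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {fmt} record: {line!r}"
                ) from exc
    return _finish(records, fmt, length, pragma_lengths, chrom)


def write_spectrum(spectrum: SolenoidalSpectrum, path) -> None:
    """Write a spectrum as TSV (period, score, pvalue, neglog10p)."""
    df = pd.DataFrame(
        {
            "period": spectrum.periods,
            "score": spectrum.scores,
            "pvalue": spectrum.pvalues if spectrum.calibrated else np.nan,
            "neglog10p": spectrum.neglog10p if spectrum.calibrated else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spectrum(path, n_sites: int = 0, J: int = 0) -> SolenoidalSpectrum:
    """Round-trip reader for :func:`write_spectrum` output."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    calibrated = not df["pvalue"].isna().all()
    return SolenoidalSpectrum(
        periods=df["period"].to_numpy(),
        scores=df["score"].to_numpy(),
        n_sites=n_sites,
        J=J,
        pvalues=df["pvalue"].to_numpy() if calibrated else None,
        neglog10p=df["neglog10p"].to_numpy() if calibrated else None,
    )


def write_positional(table: PositionalScoreTable, path) -> None:
    """Write per-site positional scores as TSV."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_peaks(peaks: PeakSet, path) -> None:
    """Write detected peaks (one row per peak, fundamentals flagged)."""
    df = pd.DataFrame(
        [
            {
                "period": pk.period,
                "score": pk.score,
                "neglog10p": pk.neglog10p,
                "group_id": pk.group_id,
                "fundamental": int(pk.fundamental),
            }
            for pk in peaks
        ],
        columns=["period", "score", "neglog10p", "group_id", "fundamental"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_manifest(path, config: dict) -> None:
    """Write a reproducibility manifest (config, seed, versions) as JSON."""
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "versions": {
            "solscm": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
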