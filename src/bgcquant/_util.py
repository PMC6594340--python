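"""Small shared helpers (gzip-tolerant IO, Pfam accession normalization)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz`` paths."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def strip_pfam_version(accession: str) -> str:
    """Drop a trailing Pfam version suffix: ``PF00501.28`` -> ``PF00501``."""
    return accession.split(".", 1)[0].strip()
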