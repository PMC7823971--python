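"""Convenience retrieval of soft-masked assemblies from remote genome
repositories (FTP/HTTPS), with a per-species folder layout.

Only the soft-masked ("sm") FASTA variant is usable downstream: hard-
masked files replace repeats with N and destroy the lowercase signal
this tool profiles, so they are rejected outright.

Remote path layouts are configuration data (format templates), not
code; tests exercise the full download path against ``file://`` URLs,
so no network is ever required.
"""

from __future__ import annotations

import gzip
import shutil
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from .errors import FetchError

PathLike = Union[str, Path]

#: Remote filename templates per repository dialect.  ``{base}`` is the
#: repository root URL, ``{species}`` the lowercase species key,
#: ``{release}`` the release/version string.  Several candidates are
#: tried in order.
PATH_TEMPLATES: Dict[str, List[str]] = {
    "ensembl-style": [
        "{base}/release-{release}/fasta/{species}/dna/{species}.dna_sm.toplevel.fa.gz",
        "{base}/{species}/dna/{species}.dna_sm.toplevel.fa.gz",
    ],
    "ncbi-style": [
        "{base}/{species}/{species}_genomic.sm.fna.gz",
        "{base}/{species}/{species}_genomic.fna.gz",
    ],
}

#: Filename fragments that identify hard-masked variants.
_HARD_MASK_MARKERS = ("dna_rm", ".rm.", "_rm.")


@dataclass(frozen=True)
class SpeciesRequest:
    """One species to retrieve into its own folder under ``destination``."""

    species_name: str
    source: str = "ensembl-style"
    release: str = "current"
    destination: PathLike = "."
    base_url: Optional[str] = None  # overrides the template base

    def __post_init__(self) -> None:
        if self.source not in PATH_TEMPLATES:
            raise FetchError(
                f"unknown source {self.source!r}; "
                f"known: {', '.join(PATH_TEMPLATES)}"
            )

    @property
    def species_key(self) -> str:
        return self.species_name.strip().lower().replace(" ", "_")


def _candidate_urls(request: SpeciesRequest) -> List[str]:
    base = request.base_url
    if base is None:
        raise FetchError(
            "no base URL configured; pass base_url (repository root) explicitly"
        )
    return [
        template.format(
            base=base.rstrip("/"),
            species=request.species_key,
            release=request.release,
        )
        for template in PATH_TEMPLATES[request.source]
    ]


def _download(url: str, target: Path) -> None:
    """Stream ``url`` to ``target`` atomically, verifying size if known."""
    tmp = target.with_suffix(target.suffix + ".part")
    try:
        with urllib.request.urlopen(url) as response:
            expected = response.headers.get("Content-Length")
            with open(tmp, "wb") as out:
                shutil.copyfileobj(response, out)
        if expected is not None and tmp.stat().st_size != int(expected):
            tmp.unlink(missing_ok=True)
            raise FetchError(
                f"partial download of {url}: got {tmp.stat().st_size} bytes, "
                f"expected {expected}"
            )
        tmp.rename(target)
    except (urllib.error.URLError, OSError) as exc:
        tmp.unlink(missing_ok=True)
        raise FetchError(f"transfer failed for {url}: {exc}") from exc


def fetch_assembly(request: SpeciesRequest) -> Path:
    """Fetch one species' soft-masked FASTA; returns the local path.

    The archive lands in ``<destination>/<species>/`` and is decompressed
    in place.  Idempotent: an existing decompressed file short-circuits
    the download.  Unresolvable species raise a :class:`FetchError`
    listing every attempted remote path.
    """
    species_dir = Path(request.destination) / request.species_key
    species_dir.mkdir(parents=True, exist_ok=True)

    attempted = []
    for url in _candidate_urls(request):
        name = url.rsplit("/", 1)[-1]
        if any(marker in name for marker in _HARD_MASK_MARKERS):
            raise FetchError(
                f"{name} is a hard-masked (rm) variant; soft-masked (sm) FASTA "
                "is required because lowercase repeat annotation is the "
                "profiling substrate"
            )
        final = species_dir / (name[:-3] if name.endswith(".gz") else name)
        if final.exists() and final.stat().st_size > 0:
            return final  # idempotent skip
        archive = species_dir / name
        try:
            _download(url, archive)
        except FetchError as exc:
            attempted.append(f"{url} ({exc})")
            continue
        if archive.suffix == ".gz":
            with gzip.open(archive, "rb") as src, open(final, "wb") as dst:
                shutil.copyfileobj(src, dst)
            archive.unlink()
        return final
    raise FetchError(
        f"could not resolve species {request.species_name!r}; attempted:\n  "
        + "\n  ".join(attempted)
    )
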