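"""File formats and serialization.

Two text formats are defined:

* **Case-encoded masked superstring FASTA** — the interchange format: one
  record whose header carries ``k=<int> model=<uni|bi>`` and whose sequence
  encodes the mask in letter case (uppercase = mask 1, lowercase = mask 0).
  This is the one bit-exact external format.
* **Index archive** — a small versioned text file storing the masked
  superstring plus metadata (mode, policy, kLCP flag); all derived
  structures (suffix array, BWT, rank/select, kLCP) are deterministically
  rebuilt on load, which keeps the archive simple and version-proof.

Plain FASTA ingestion is gzip-transparent and delegates record parsing to
Biopython.
"""

from __future__ import annotations

import gzip
import io as _io

from Bio import SeqIO

from .kmers import StrandModel
from .superstring import MaskedSuperstring, MaskPolicy
from .index import SuperstringIndex, build_index

__all__ = [
    "FastaParseError",
    "FormatError",
    "ArchiveError",
    "read_fasta",
    "write_masked_superstring",
    "read_masked_superstring",
    "save_index",
    "load_index",
]

ARCHIVE_MAGIC = "#MSINDEX"
ARCHIVE_VERSION = 1


class FastaParseError(ValueError):
    pass


class FormatError(ValueError):
    pass


class ArchiveError(ValueError):
    pass


def _open_text(path) -> _io.TextIOBase:
    """Open a possibly-gzipped text file (detected by magic bytes)."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw), newline=None)
    return _io.TextIOWrapper(raw, newline=None)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (name, SEQUENCE) tuples.

    Sequence case is normalized upward; CRLF line endings are tolerated.
    A malformed file raises :class:`FastaParseError` with the line number.
    """
    with _open_text(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected '>' header, got {line[:20]!r}"
            )
        break
    records = SeqIO.parse(_io.StringIO(text), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


# ---------------------------------------------------------------------------
# Case-encoded masked superstring format
# ---------------------------------------------------------------------------

def _case_encode(ms: MaskedSuperstring) -> str:
    return "".join(
        ch.upper() if bit == "1" else ch.lower() for ch, bit in zip(ms.S, ms.M)
    )


def write_masked_superstring(ms: MaskedSuperstring, path) -> None:
    """Write a masked superstring as case-encoded FASTA."""
    header = (
        f">superstring k={ms.k} model={ms.model.value} policy={ms.policy.value}"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        body = _case_encode(ms)
        for p in range(0, len(body), 80):
            fh.write(body[p : p + 80] + "\n")
        if not body:
            fh.write("\n")


def _parse_ms_header(header: str, path) -> tuple[int, StrandModel, MaskPolicy]:
    fields = dict(
        tok.split("=", 1) for tok in header[1:].split() if "=" in tok
    )
    if "k" not in fields:
        raise FormatError(f"{path}: masked-superstring header missing k=")
    if "model" not in fields:
        raise FormatError(f"{path}: masked-superstring header missing model=")
    try:
        k = int(fields["k"])
        model = StrandModel(fields["model"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad header field: {exc}") from exc
    policy = MaskPolicy(fields.get("policy", "unoptimized"))
    return k, model, policy


def read_masked_superstring(path) -> MaskedSuperstring:
    """Read a case-encoded masked superstring (inverse of the writer)."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() or ln == ""]
    header = None
    body_parts: list[str] = []
    for ln in lines:
        if ln.startswith(">"):
            if header is not None:
                raise FormatError(f"{path}: expected a single record")
            header = ln
        elif header is not None:
            body_parts.append(ln.strip())
        elif ln.strip():
            raise FormatError(f"{path}: data before header")
    if header is None:
        raise FormatError(f"{path}: no masked-superstring record found")
    k, model, policy = _parse_ms_header(header, path)
    body = "".join(body_parts)
    bad = set(body) - set("ACGTacgt")
    if bad:
        raise FormatError(f"{path}: letter(s) {sorted(bad)!r} outside alphabet")
    S = body.upper()
    M = "".join("1" if ch.isupper() else "0" for ch in body)
    return MaskedSuperstring(k=k, model=model, S=S, M=M, policy=policy)


# ---------------------------------------------------------------------------
# Index archive
# ---------------------------------------------------------------------------

def save_index(index: SuperstringIndex, path) -> None:
    """Serialize an index: metadata plus the case-encoded masked superstring.

    Derived structures are rebuilt on load, so the archive is plain text.
    """
    from .mbwt import invert_mbwt

    ms = invert_mbwt(index.image)
    body = _case_encode(ms)
    with open(path, "w") as fh:
        fh.write(
            f"{ARCHIVE_MAGIC} version={ARCHIVE_VERSION} k={index.k} "
            f"model={index.model.value} mode={index.mode} "
            f"policy={index.image.policy.value} "
            f"klcp={1 if index.klcp is not None else 0} length={len(body)}\n"
        )
        for p in range(0, len(body), 80):
            fh.write(body[p : p + 80] + "\n")
        fh.write("#END\n")


def load_index(path) -> SuperstringIndex:
    """Load an archive and deterministically rebuild the index."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(ARCHIVE_MAGIC + " "):
        raise ArchiveError(f"{path}: not an index archive (bad magic)")
    fields = dict(tok.split("=", 1) for tok in lines[0].split()[1:] if "=" in tok)
    try:
        version = int(fields["version"])
        k = int(fields["k"])
        model = StrandModel(fields["model"])
        mode = fields["mode"]
        policy = MaskPolicy(fields["policy"])
        with_klcp = fields["klcp"] == "1"
        length = int(fields["length"])
    except (KeyError, ValueError) as exc:
        raise ArchiveError(f"{path}: malformed archive header: {exc}") from exc
    if version != ARCHIVE_VERSION:
        raise ArchiveError(
            f"{path}: archive version {version} not supported "
            f"(expected {ARCHIVE_VERSION})"
        )
    if not lines or lines[-1].strip() != "#END":
        raise ArchiveError(f"{path}: truncated archive (missing end marker)")
    body = "".join(ln.strip() for ln in lines[1:-1])
    if len(body) != length:
        raise ArchiveError(
            f"{path}: truncated archive (payload {len(body)} != {length})"
        )
    S = body.upper()
    M = "".join("1" if ch.isupper() else "0" for ch in body)
    ms = MaskedSuperstring(k=k, model=model, S=S, M=M, policy=policy)
    required = MaskPolicy.MAX_ONE if mode == "memb" else MaskPolicy.MIN_ONE
    return build_index(
        ms, mode, with_klcp, allow_general_mask=(policy is not required)
    )
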