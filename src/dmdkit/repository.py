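"""Versioned scheme packages and the repository index.

A *scheme package* is a zip archive ``<name>_<version>.zip`` holding the
scheme manifest (JSON), the empty template workbook, example filled
workbooks, and a package manifest with a SHA-256 checksum over the member
contents.  A *repository* is simply a directory (or a static URL serving
the same layout) with an ``index.json`` listing the available packages —
no server-side logic.  Installation unpacks an archive into a temporary
per-session directory, mirroring the original approach of loading schemes
into a throwaway library, and never mutates the repository.
"""

from __future__ import annotations

import hashlib
import io
import json
import tempfile
import urllib.request
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import IntegrityError, PackagingError, RepositoryError
from .scheme_model import (
    MetadataSet,
    Scheme,
    check_scheme_definition,
    is_prerelease,
    scheme_from_json,
    scheme_to_json,
    semver_key,
)
from .spreadsheet_io import write_filled_workbook, write_template_workbook
from .validation import validate_all

INDEX_NAME = "index.json"
PACKAGE_MANIFEST = "package.json"
SCHEME_MANIFEST = "scheme.json"
TEMPLATE_NAME = "template.xlsx"

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def content_checksum(members: dict[str, bytes]) -> str:
    """Checksum over member names and bytes, package manifest excluded."""
    h = hashlib.sha256()
    for name in sorted(members):
        if name == PACKAGE_MANIFEST:
            continue
        h.update(name.encode("utf-8"))
        h.update(b"\0")
        h.update(members[name])
        h.update(b"\0")
    return h.hexdigest()


@dataclass
class SchemePackage:
    """A packed scheme archive on disk plus its parsed manifest."""

    path: Path
    manifest: dict


@dataclass
class IndexEntry:
    name: str
    version: str
    archive: str  # path or URL relative to the index
    checksum: str
    description: str = ""


def _zip_members(path_or_bytes) -> dict[str, bytes]:
    data = (
        path_or_bytes
        if isinstance(path_or_bytes, (bytes, bytearray))
        else Path(path_or_bytes).read_bytes()
    )
    with zipfile.ZipFile(io.BytesIO(data)) as zf:
        return {info.filename: zf.read(info.filename) for info in zf.infolist()}


def _write_zip(path: Path, members: dict[str, bytes]) -> None:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zf.writestr(info, members[name])
    path.write_bytes(buf.getvalue())


def pack_scheme(
    scheme: Scheme,
    examples: list[MetadataSet],
    out_dir,
) -> SchemePackage:
    """Pack a scheme plus example metadata into ``<name>_<version>.zip``.

    Packing is refused when the scheme is ill-formed or any example fails
    validation with error-level issues (data-file checks are not run: the
    examples travel without their data).
    """
    problems = check_scheme_definition(scheme)
    if problems:
        raise PackagingError("scheme is not well-formed: " + "; ".join(problems))
    for i, example in enumerate(examples, start=1):
        report = validate_all(example, scheme)
        n = report.counts()["error"]
        if n:
            raise PackagingError(
                f"example {i} has {n} validation error(s); packaging refused"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    members: dict[str, bytes] = {
        SCHEME_MANIFEST: scheme_to_json(scheme).encode("utf-8")
    }
    with tempfile.TemporaryDirectory(prefix="dmdkit-pack-") as tmp:
        tpath = Path(tmp) / TEMPLATE_NAME
        write_template_workbook(scheme, tpath)
        members[TEMPLATE_NAME] = tpath.read_bytes()
        for i, example in enumerate(examples, start=1):
            epath = Path(tmp) / f"example_{i:02d}.xlsx"
            write_filled_workbook(scheme, example, epath)
            members[f"examples/example_{i:02d}.xlsx"] = epath.read_bytes()
    manifest = {
        "name": scheme.name,
        "version": scheme.version,
        "description": scheme.description,
        "checksum": content_checksum(members),
    }
    members[PACKAGE_MANIFEST] = (
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    ).encode("utf-8")
    archive = out_dir / f"{scheme.name}_{scheme.version}.zip"
    _write_zip(archive, members)
    return SchemePackage(path=archive, manifest=manifest)


def build_index(repo_dir) -> list[IndexEntry]:
    """Scan ``repo_dir`` for packages and (re)write its ``index.json``."""
    repo_dir = Path(repo_dir)
    entries: list[IndexEntry] = []
    for archive in sorted(repo_dir.glob("*.zip")):
        members = _zip_members(archive)
        if PACKAGE_MANIFEST not in members:
            continue
        manifest = json.loads(members[PACKAGE_MANIFEST])
        entries.append(IndexEntry(
            name=manifest["name"],
            version=manifest["version"],
            archive=archive.name,
            checksum=_sha256(archive.read_bytes()),
            description=manifest.get("description", ""),
        ))
    entries = _sort_entries(entries)
    (repo_dir / INDEX_NAME).write_text(
        json.dumps([e.__dict__ for e in entries], indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return entries


def _sort_entries(entries: list[IndexEntry]) -> list[IndexEntry]:
    def key(e: IndexEntry):
        try:
            v = semver_key(e.version)
        except Exception:
            v = (0, 0, 0)
        return (e.name, tuple(-x for x in v))

    return sorted(entries, key=key)


def _is_url(uri: str) -> bool:
    return isinstance(uri, str) and uri.split(":", 1)[0] in ("http", "https", "file")


def _fetch(uri: str) -> bytes:
    if _is_url(uri):
        with urllib.request.urlopen(uri) as resp:  # static hosting only
            return resp.read()
    return Path(uri).read_bytes()


def list_schemes(repo_uri) -> list[IndexEntry]:
    """Parse the repository index; entries sorted by name, version descending."""
    repo_uri = str(repo_uri)
    index_uri = (
        f"{repo_uri.rstrip('/')}/{INDEX_NAME}"
        if _is_url(repo_uri)
        else str(Path(repo_uri) / INDEX_NAME)
    )
    try:
        raw = _fetch(index_uri)
    except OSError as exc:
        raise RepositoryError(f"repository index unreachable: {index_uri} ({exc})") from exc
    try:
        data = json.loads(raw)
        entries = [IndexEntry(**e) for e in data]
    except (json.JSONDecodeError, TypeError, KeyError) as exc:
        raise RepositoryError(f"corrupt repository index: {index_uri} ({exc})") from exc
    seen: set[tuple[str, str]] = set()
    for e in entries:
        if (e.name, e.version) in seen:
            raise RepositoryError(
                f"duplicate index entry: {e.name} {e.version}"
            )
        seen.add((e.name, e.version))
    return _sort_entries(entries)


@dataclass
class InstalledScheme:
    scheme: Scheme
    directory: Path
    paths: dict[str, Path]


def install_scheme(
    repo_uri,
    name: str,
    version: str = "latest",
    dest_dir=None,
) -> InstalledScheme:
    """Fetch, verify and unpack a scheme package; return the loaded scheme.

    ``version="latest"`` resolves by numeric semver ordering, pre-release
    tags excluded.  The archive checksum (index) and the member-content
    checksum (package manifest) must both verify.
    """
    entries = [e for e in list_schemes(repo_uri) if e.name == name]
    if not entries:
        raise RepositoryError(f"no scheme named {name!r} in repository")
    if version == "latest":
        releases = [e for e in entries if not is_prerelease(e.version)]
        if not releases:
            raise RepositoryError(f"no release version of {name!r} available")
        entry = max(releases, key=lambda e: semver_key(e.version))
    else:
        matches = [e for e in entries if e.version == version]
        if not matches:
            raise RepositoryError(f"no version {version!r} of scheme {name!r}")
        entry = matches[0]

    archive_uri = (
        f"{str(repo_uri).rstrip('/')}/{entry.archive}"
        if _is_url(str(repo_uri))
        else str(Path(repo_uri) / entry.archive)
    )
    try:
        blob = _fetch(archive_uri)
    except OSError as exc:
        raise RepositoryError(f"archive unreachable: {archive_uri} ({exc})") from exc
    if _sha256(blob) != entry.checksum:
        raise IntegrityError(
            f"archive checksum mismatch for {entry.name} {entry.version}"
        )
    members = _zip_members(blob)
    try:
        manifest = json.loads(members[PACKAGE_MANIFEST])
    except (KeyError, json.JSONDecodeError) as exc:
        raise RepositoryError(f"package manifest missing or corrupt: {exc}") from exc
    if content_checksum(members) != manifest.get("checksum"):
        raise IntegrityError(
            f"package content checksum mismatch for {entry.name} {entry.version}"
        )

    if dest_dir is None:
        dest_dir = tempfile.mkdtemp(prefix=f"dmdkit-{entry.name}-")
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for member, data in members.items():
        target = dest / member
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        paths[member] = target
    scheme = scheme_from_json(members[SCHEME_MANIFEST].decode("utf-8"))
    return InstalledScheme(scheme=scheme, directory=dest, paths=paths)
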