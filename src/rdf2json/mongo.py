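"""Document-store safety: field-name sanitization and import-file export.

MongoDB field names cannot contain ``.`` or the NUL character and cannot
start with ``$``.  Offending characters are replaced with fullwidth Unicode
homoglyphs (U+FF0E for ``.``, U+FF04 for a leading ``$``), which keeps the
keys human-readable; NUL is removed outright.  Sanitization is idempotent
and injective on the forbidden characters, and a collision between two
distinct keys after rewriting raises instead of silently merging them.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import ContractError, KeyCollisionError, OutputError, ValidationError
from .output import serialize

FULLWIDTH_FULL_STOP = "．"
FULLWIDTH_DOLLAR = "＄"


@dataclass(frozen=True)
class SanitizationMap:
    """Replacement characters for the forbidden field-name characters."""

    dot: str = FULLWIDTH_FULL_STOP
    leading_dollar: str = FULLWIDTH_DOLLAR

    def __post_init__(self) -> None:
        for ch in (self.dot, self.leading_dollar):
            if len(ch) != 1 or ch in ".$\x00":
                raise ValidationError(
                    "replacement must be a single character outside the forbidden set"
                )
        if self.dot == self.leading_dollar:
            raise ValidationError("replacements must be distinct (injective mapping)")


DEFAULT_SANITIZATION = SanitizationMap()


def sanitize_field_name(name: str, smap: SanitizationMap = DEFAULT_SANITIZATION) -> str:
    """Rewrite one field name so the document store accepts it."""
    s = name.replace("\x00", "").replace(".", smap.dot)
    if s.startswith("$"):
        s = smap.leading_dollar + s[1:]
    return s


def _is_forbidden(name: str) -> bool:
    return "." in name or "\x00" in name or name.startswith("$")


def sanitize_document(doc: dict, smap: SanitizationMap = DEFAULT_SANITIZATION) -> dict:
    """Sanitize every object key at every depth; values are left untouched.

    Implemented with an explicit stack so arbitrarily deep documents are
    handled.  Raises :class:`KeyCollisionError` if two distinct keys would
    collide after rewriting.
    """

    def shell(v):
        if isinstance(v, dict):
            return {}
        if isinstance(v, list):
            return []
        return v

    root = shell(doc)
    if not isinstance(doc, (dict, list)):
        return doc
    stack = [(doc, root)]
    while stack:
        src, dst = stack.pop()
        if isinstance(src, dict):
            seen: dict = {}
            for k, v in src.items():
                sk = sanitize_field_name(k, smap)
                if sk in seen:
                    raise KeyCollisionError(
                        f"keys {seen[sk]!r} and {k!r} both sanitize to {sk!r}"
                    )
                seen[sk] = k
                nv = shell(v)
                dst[sk] = nv
                if isinstance(v, (dict, list)):
                    stack.append((v, nv))
        else:
            for v in src:
                nv = shell(v)
                dst.append(nv)
                if isinstance(v, (dict, list)):
                    stack.append((v, nv))
    return root


def _find_forbidden_key(value) -> Optional[str]:
    stack = [value]
    while stack:
        v = stack.pop()
        if isinstance(v, dict):
            for k, x in v.items():
                if _is_forbidden(k):
                    return k
                stack.append(x)
        elif isinstance(v, list):
            stack.extend(v)
    return None


def write_import_file(doc: dict, path, embed_ns: bool = False) -> int:
    """Write a sanitized root document as a JSON Lines import file.

    One line per resource; each record is the resource object with a
    leading ``"uri"`` field holding the subject key (and, with
    ``embed_ns``, an ``"@ns"`` field holding the namespace map).  Returns
    the number of lines written.
    """
    resources = doc.get("resources", {})
    namespaces = doc.get("namespaces", {})
    lines = []
    for key, robj in resources.items():
        if _is_forbidden(key):
            raise ContractError(f"unsanitized resource key {key!r}; sanitize first")
        bad = _find_forbidden_key(robj)
        if bad is not None:
            raise ContractError(f"unsanitized field name {bad!r}; sanitize first")
        if isinstance(robj, dict) and "uri" in robj:
            raise ValidationError(
                f"resource {key!r} already has a 'uri' field; cannot augment"
            )
        record = {"uri": key}
        if embed_ns:
            record["@ns"] = namespaces
        if isinstance(robj, dict):
            record.update(robj)
        else:
            record["value"] = robj
        lines.append(serialize(record, "minified").decode("utf-8"))
    text = "\n".join(lines) + ("\n" if lines else "")
    try:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc
    return len(lines)


def build_import_command(db: str, coll: str, file) -> str:
    """Render the mongoimport command line for an import file."""
    if not db or not coll:
        raise ValidationError("database and collection names must be non-empty")
    return (
        f"mongoimport -d {shlex.quote(db)} -c {shlex.quote(coll)} "
        f"--file {shlex.quote(str(file))}"
    )
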