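"""The shared ``key = value`` configuration dialect.

One dialect serves every subcommand (extract / analyse / simulate):
lines of ``key = value``, blank lines and ``#`` comments ignored, later
keys overriding earlier ones.  Values are kept as strings; typed access
helpers interpret them on demand.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

__all__ = ["parse_config", "read_config", "write_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration line or key."""


def parse_config(text: str, source: str = "<config>") -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{source}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"{source}:{lineno}: empty key")
        out[key] = value
    return out


def read_config(path) -> dict[str, str]:
    path = Path(path)
    return parse_config(path.read_text(), source=str(path))


def write_config(values: Mapping[str, object], path, header: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {header}"] if header else []
    lines += [f"{k} = {v}" for k, v in values.items()]
    path.write_text("\n".join(lines) + "\n")
    return path
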