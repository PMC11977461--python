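"""Table readers and writers: TSV with '#'-prefixed comment headers.

All tables are UTF-8 TSV with '.' as the decimal separator.  Intensity
tables are accepted wide (first column the sample id, remaining columns
protein groups) or long (columns sample, protein_group, intensity),
auto-detected from the header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

LONG_COLUMNS = {"sample", "protein_group", "intensity"}


def read_intensities(path: str | Path) -> pd.DataFrame:
    """Read a wide or long intensity table into samples x protein groups."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    if set(frame.columns) == LONG_COLUMNS:
        wide = frame.pivot(index="sample", columns="protein_group", values="intensity")
        wide = wide.fillna(0.0)
        wide.columns.name = None
        return wide
    return frame.set_index(frame.columns[0]).rename_axis("sample")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Samples x features table (SCFA panel, metabolites, profiles)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame.set_index(frame.columns[0]).rename_axis("sample")


def write_profile(profile: pd.DataFrame, path: str | Path) -> Path:
    """Write a profile with its feature kind as a comment header."""
    path = Path(path)
    kind = profile.attrs.get("kind", "unknown")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={kind}\n")
        if "species" in profile.attrs:
            fh.write(f"# species={profile.attrs['species']}\n")
        profile.to_csv(fh, sep="\t")
    return path


def read_profile(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    attrs = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            attrs[key.strip()] = value.strip()
    profile = read_feature_table(path)
    profile.attrs.update(attrs)
    return profile


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=index)
    return path
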