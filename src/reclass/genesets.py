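"""GMT gene-set file reading and writing.

One set per line: name, description, then member genes, tab-separated.
"""

from __future__ import annotations


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered ``{name: [genes]}`` mapping."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
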