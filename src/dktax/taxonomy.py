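"""NCBI-style taxonomy: parent-pointer tree, rank projection, LCA.

Two on-disk dialects are supported: the NCBI dump format (nodes.dmp /
names.dmp, fields separated by ``\\t|\\t``) and a simplified 4-column TSV
(taxid, parent, rank, name) used for fixtures and for the copy of the
taxonomy embedded in a built database.  Only the *species* and *genus*
ranks are interpreted by the algorithms; all other rank labels are carried
through untouched.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .errors import CycleError, FormatError, UnknownTaxidError


@dataclass
class TaxonomyTree:
    """Rank-annotated parent-pointer tree over integer taxonomy IDs."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str] = field(default_factory=dict)
    root: int = 1

    def __post_init__(self) -> None:
        self._depth_cache: dict[int, int] = {self.root: 0}

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def _require(self, taxid: int) -> None:
        if taxid not in self.parent:
            raise UnknownTaxidError(f"taxid {taxid} not in taxonomy")

    def validate(self) -> None:
        """Check every node reaches the root without cycles or orphans."""
        for taxid in self.parent:
            self.lineage(taxid)

    def lineage(self, taxid: int) -> list[int]:
        """Path from ``taxid`` up to and including the root."""
        self._require(taxid)
        path = [taxid]
        seen = {taxid}
        node = taxid
        while node != self.root:
            parent = self.parent.get(node)
            if parent is None:
                raise CycleError(f"taxid {node} has no parent record")
            if parent in seen:
                raise CycleError(f"cycle detected at taxid {parent}")
            seen.add(parent)
            path.append(parent)
            node = parent
        return path

    def depth(self, taxid: int) -> int:
        cached = self._depth_cache.get(taxid)
        if cached is not None:
            return cached
        d = len(self.lineage(taxid)) - 1
        self._depth_cache[taxid] = d
        return d

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (or self) at the requested rank, else None."""
        for node in self.lineage(taxid):
            if self.rank.get(node) == rank:
                return node
        return None

    def lca(self, a: int, b: int) -> int:
        """Deepest common ancestor of two taxa."""
        ancestors = set(self.lineage(a))
        for node in self.lineage(b):
            if node in ancestors:
                return node
        return self.root  # unreachable for a validated tree

    def lca_many(self, taxids) -> int:
        taxids = list(taxids)
        node = taxids[0]
        for other in taxids[1:]:
            node = self.lca(node, other)
        return node


def ancestor_at_rank(tree: TaxonomyTree, taxid: int, rank: str) -> int | None:
    return tree.ancestor_at_rank(taxid, rank)


def lca(tree: TaxonomyTree, a: int, b: int) -> int:
    return tree.lca(a, b)


def _split_dmp(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def load_taxonomy(nodes_source: str, names_source: str | None = None) -> TaxonomyTree:
    """Load a taxonomy from NCBI dumps or the simplified TSV.

    ``nodes_source`` may be a nodes.dmp path (with ``names_source`` the
    matching names.dmp), a directory containing nodes.dmp/names.dmp or
    taxonomy.tsv, or a simplified TSV path directly.
    """
    if os.path.isdir(nodes_source):
        tsv = os.path.join(nodes_source, "taxonomy.tsv")
        if os.path.exists(tsv):
            return load_taxonomy_tsv(tsv)
        nodes = os.path.join(nodes_source, "nodes.dmp")
        names = os.path.join(nodes_source, "names.dmp")
        if not os.path.exists(nodes):
            raise FormatError(f"no taxonomy found under {nodes_source}")
        return load_taxonomy(nodes, names if os.path.exists(names) else None)
    if nodes_source.endswith(".tsv"):
        return load_taxonomy_tsv(nodes_source)

    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    with open(nodes_source) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise FormatError(f"{nodes_source}:{ln}: expected >=3 dmp fields")
            try:
                taxid, par = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{nodes_source}:{ln}: non-integer taxid") from exc
            parent[taxid] = par
            rank[taxid] = fields[2]

    name: dict[int, str] = {}
    if names_source is not None:
        with open(names_source) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dmp(line)
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                name[int(fields[0])] = fields[1]

    return _finalize(parent, rank, name)


def load_taxonomy_tsv(path: str) -> TaxonomyTree:
    """Load the simplified dialect: taxid<TAB>parent<TAB>rank<TAB>name."""
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    name: dict[int, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 tab-separated fields")
            try:
                taxid, par = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer taxid") from exc
            parent[taxid] = par
            rank[taxid] = fields[2]
            if len(fields) > 3:
                name[taxid] = fields[3]
    return _finalize(parent, rank, name)


def _finalize(parent: dict[int, int], rank: dict[int, str], name: dict[int, str]) -> TaxonomyTree:
    if not parent:
        raise FormatError("empty taxonomy")
    roots = [t for t, p in parent.items() if p == t or p == 0]
    if len(roots) != 1:
        raise FormatError(f"expected exactly one root, found {roots}")
    root = roots[0]
    parent[root] = root
    tree = TaxonomyTree(parent=parent, rank=rank, name=name, root=root)
    # reject orphans / cycles up front
    for taxid in parent:
        path = [taxid]
        seen = {taxid}
        node = taxid
        while node != root:
            par = parent.get(node)
            if par is None:
                raise FormatError(f"taxid {node} references absent parent")
            if par in seen:
                raise CycleError(f"cycle through taxid {par}")
            seen.add(par)
            node = par
    return tree


def write_taxonomy_tsv(tree: TaxonomyTree, path: str) -> None:
    with open(path, "w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(
                f"{taxid}\t{tree.parent[taxid]}\t{tree.rank.get(taxid, 'no rank')}"
                f"\t{tree.name.get(taxid, '')}\n"
            )


def load_seqtax_map(path: str, tree: TaxonomyTree | None = None) -> dict[str, int]:
    """Load a 2-column TSV mapping sequence ID -> taxid.

    Sequence IDs are the first whitespace-delimited token of the FASTA
    header.  When a tree is given, every mapped taxid must exist in it.
    """
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: expected seqid<TAB>taxid")
            try:
                taxid = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer taxid") from exc
            if tree is not None and taxid not in tree:
                raise UnknownTaxidError(f"{path}:{ln}: taxid {taxid} not in taxonomy")
            mapping[fields[0].split()[0]] = taxid
    return mapping


def write_seqtax_map(mapping: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for seqid in sorted(mapping):
            fh.write(f"{seqid}\t{mapping[seqid]}\n")
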