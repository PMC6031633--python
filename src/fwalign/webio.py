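"""Reading, validating and writing food webs and dataset manifests.

A food web is a directed graph whose links point in the direction of
energy flow: ``(resource, consumer)``.  Webs are stored as edge lists
(TSV) or square adjacency matrices (CSV with species labels on the first
row and column).  A dataset manifest maps web ids to files and ecosystem
labels and enforces the species-count inclusion window used for
community datasets (5-133 species by default).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

log = logging.getLogger(__name__)

ECOSYSTEMS = frozenset({"estuary", "lake", "marine", "stream", "terrestrial"})

#: Default inclusion window on species counts for community datasets.
SIZE_FILTER = (5, 133)


class FoodWebError(ValueError):
    """Malformed food-web input."""


@dataclass
class FoodWeb:
    """A labeled directed food web.

    Parameters
    ----------
    id : str
        Identifier of the web, unique within a dataset.
    species : sequence of str
        Ordered species labels.  Order is preserved through I/O and used
        for deterministic output.
    links : iterable of (str, str)
        Directed links ``(resource, consumer)``; duplicates collapse to
        one link (a warning is logged).
    weights : mapping, optional
        Interaction strengths, keyed by link.
    ecosystem : str, optional
        One of estuary / lake / marine / stream / terrestrial, or None.
    """

    id: str
    species: tuple = ()
    links: frozenset = frozenset()
    weights: dict = field(default_factory=dict)
    ecosystem: str | None = None

    def __init__(self, id, species, links, weights=None, ecosystem=None):
        self.id = str(id)
        self.species = tuple(dict.fromkeys(str(s) for s in species))
        seen = set()
        dup = 0
        for r, c in links:
            e = (str(r), str(c))
            if e in seen:
                dup += 1
            seen.add(e)
        if dup:
            log.warning("web %s: %d duplicate link(s) collapsed", self.id, dup)
        self.links = frozenset(seen)
        sp = set(self.species)
        bad = [e for e in self.links if e[0] not in sp or e[1] not in sp]
        if bad:
            raise FoodWebError(
                f"web {self.id}: link endpoints not in species list: {sorted(bad)[:3]}"
            )
        if not self.species:
            raise FoodWebError(f"web {self.id}: at least one species required")
        self.weights = {} if weights is None else {
            (str(r), str(c)): float(w) for (r, c), w in weights.items()
        }
        extra = set(self.weights) - self.links
        if extra:
            raise FoodWebError(f"web {self.id}: weights for unknown links {sorted(extra)[:3]}")
        if ecosystem is not None and ecosystem not in ECOSYSTEMS and ecosystem != "unknown":
            raise FoodWebError(f"web {self.id}: unknown ecosystem label {ecosystem!r}")
        self.ecosystem = ecosystem
        if any(r == c for r, c in self.links):
            log.warning("web %s: contains self-loops (cannibalism); they are "
                        "ignored by motif counting and alignment", self.id)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def has_self_loops(self) -> bool:
        return any(r == c for r, c in self.links)

    def without_self_loops(self) -> "FoodWeb":
        """Copy with cannibalistic links removed (motif/alignment input)."""
        if not self.has_self_loops():
            return self
        links = [e for e in self.links if e[0] != e[1]]
        w = {e: self.weights[e] for e in links if e in self.weights}
        return FoodWeb(self.id, self.species, links, w, self.ecosystem)

    def relabeled(self, mapping: Mapping[str, str], new_id: str | None = None) -> "FoodWeb":
        """Copy with species renamed through ``mapping``."""
        sp = [mapping[s] for s in self.species]
        links = [(mapping[r], mapping[c]) for r, c in self.links]
        w = {(mapping[r], mapping[c]): v for (r, c), v in self.weights.items()}
        return FoodWeb(new_id or self.id, sp, links, w, self.ecosystem)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for r, c in self.links:
            g.add_edge(r, c, weight=self.weights.get((r, c), 1.0))
        return g

    def neighbors(self, s: str) -> frozenset:
        """Union of prey and predators of ``s`` (self excluded)."""
        out = set()
        for r, c in self.links:
            if r == s and c != s:
                out.add(c)
            elif c == s and r != s:
                out.add(r)
        return frozenset(out)

    def __eq__(self, other):
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return (set(self.species) == set(other.species)
                and self.links == other.links
                and self.weights == other.weights)

    def __repr__(self):
        return f"FoodWeb({self.id!r}, S={self.n_species}, L={self.n_links})"


@dataclass
class DatasetManifest:
    entries: list  # (web_id, path, ecosystem)
    size_filter: tuple = SIZE_FILTER

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise FoodWebError("duplicate web_id in manifest")
        for wid, _, eco in self.entries:
            if eco not in ECOSYSTEMS and eco != "unknown":
                raise FoodWebError(f"manifest entry {wid}: bad ecosystem {eco!r}")


def _parse_edgelist(path: Path, web_id: str, weighted: bool) -> FoodWeb:
    links, weights = [], {}
    declared: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("# species:"):
                declared = line[len("# species:"):].split()
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FoodWebError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
            r, c = parts[0], parts[1]
            links.append((r, c))
            if len(parts) >= 3:
                try:
                    weights[(r, c)] = float(parts[2])
                except ValueError as exc:
                    raise FoodWebError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
    species = declared or list(dict.fromkeys(s for e in links for s in e))
    extra = [s for e in links for s in e if s not in set(species)]
    species = species + list(dict.fromkeys(extra))
    return FoodWeb(web_id, species, links, weights or None)


def _parse_adjacency(path: Path, web_id: str) -> FoodWeb:
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and not row[0].startswith("#")]
    if not rows:
        raise FoodWebError(f"{path}: empty adjacency file")
    header = [h.strip() for h in rows[0][1:]]
    n = len(header)
    if len(rows) - 1 != n:
        raise FoodWebError(
            f"{path}: non-square adjacency ({len(rows) - 1} rows vs {n} columns)")
    links, weights = [], {}
    for i, row in enumerate(rows[1:]):
        label = row[0].strip()
        if label != header[i]:
            raise FoodWebError(
                f"{path}: row label {label!r} does not match column header {header[i]!r}")
        if len(row) - 1 != n:
            raise FoodWebError(f"{path}: row {label!r} has {len(row) - 1} entries, expected {n}")
        for j, cell in enumerate(row[1:]):
            v = float(cell) if cell.strip() else 0.0
            if v != 0.0:
                links.append((label, header[j]))
                weights[(label, header[j])] = v
    uniform = all(w == 1.0 for w in weights.values())
    return FoodWeb(web_id, header, links, None if uniform else weights)


def load_web(path, format: str = "edgelist", web_id: str | None = None,
             weighted: bool = True) -> FoodWeb:
    """Load a food web from ``path``.

    ``format`` is ``"edgelist"`` (TSV resource/consumer[/weight]) or
    ``"adjacency"`` (CSV, labels on first row and column, entry (i, j)
    nonzero meaning a link i -> j).  Isolated species present in
    adjacency headers are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wid = web_id or path.stem
    if format == "edgelist":
        return _parse_edgelist(path, wid, weighted)
    if format == "adjacency":
        return _parse_adjacency(path, wid)
    raise ValueError(f"unknown format {format!r}")


def save_web(web: FoodWeb, path, format: str = "edgelist") -> None:
    """Write ``web`` so that :func:`load_web` round-trips it exactly."""
    path = Path(path)
    if format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# food web {web.id}\n")
            # species directive preserves ordering and isolated species
            fh.write("# species: " + " ".join(web.species) + "\n")
            for r, c in sorted(web.links):
                if web.weights:
                    fh.write(f"{r}\t{c}\t{web.weights.get((r, c), 1.0):.17g}\n")
                else:
                    fh.write(f"{r}\t{c}\n")
    elif format == "adjacency":
        sp = list(web.species)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow([""] + sp)
            for r in sp:
                row = [r]
                for c in sp:
                    if (r, c) in web.links:
                        row.append(f"{web.weights.get((r, c), 1.0):.17g}")
                    else:
                        row.append("0")
                wr.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def is_bipartite_like(web: FoodWeb) -> bool:
    """Heuristic flag for bipartite interaction networks.

    True when the species partition into two classes with links only
    across classes and one class entirely basal (no outgoing links).
    Such networks are reported (the alignment method targets unipartite
    webs) but not auto-excluded.
    """
    g = web.without_self_loops().to_networkx()
    und = g.to_undirected()
    if not nx.is_bipartite(und):
        return False
    consumers = {c for _, c in web.links}
    resources = {r for r, _ in web.links}
    basal = resources - consumers
    # one side of the two-coloring must be all-basal
    try:
        left, right = nx.bipartite.sets(und)
    except nx.AmbiguousSolution:
        return False
    return (not (left & consumers)) or (not (right & consumers))


def load_manifest(path, enforce_size_filter: bool = True,
                  size_filter: tuple = SIZE_FILTER):
    """Load a dataset manifest and all webs it references.

    Returns ``(manifest, webs, excluded)`` where ``excluded`` lists
    ``(web_id, reason)`` for webs outside the species-count window.
    Bipartite-looking webs are warned about but kept.
    """
    path = Path(path)
    base = path.parent
    entries = []
    with open(path, encoding="utf-8") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        need = {"web_id", "path", "ecosystem"}
        if rd.fieldnames is None or not need <= set(rd.fieldnames):
            raise FoodWebError(f"{path}: manifest needs columns {sorted(need)}")
        for row in rd:
            entries.append((row["web_id"], row["path"], row["ecosystem"] or "unknown"))
    manifest = DatasetManifest(entries, size_filter)
    webs, excluded = [], []
    lo, hi = size_filter
    for wid, rel, eco in entries:
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest entry {wid!r}: no such file {p}")
        fmt = "adjacency" if p.suffix.lower() == ".csv" else "edgelist"
        web = load_web(p, format=fmt, web_id=wid)
        web.ecosystem = eco
        if enforce_size_filter and not lo <= web.n_species <= hi:
            excluded.append((wid, f"{web.n_species} species outside [{lo}, {hi}]"))
            log.info("excluding web %s: %s", wid, excluded[-1][1])
            continue
        if is_bipartite_like(web):
            log.warning("web %s looks bipartite; the alignment method targets "
                        "unipartite webs", wid)
        webs.append(web)
    return manifest, webs, excluded
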