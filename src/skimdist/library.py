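"""Reference libraries of sketched skims, ranked query, leave-out metrics.

A library is a plain directory: one subdirectory per sample holding the
sketch (gzipped text) and the estimated profile (key=value text), plus a
JSON manifest pinning the shared parameters (k, sketch size, hash seed).
Queries are ranked by the corrected distance, ascending, ties broken by
name, so searches are deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .distance import DEFAULT_K, skim_distance
from .kmers import count_kmers, histogram, read_sequences
from .profile import SkimProfile, build_profile
from .sketch import DEFAULT_HASH_SEED, DEFAULT_SKETCH_SIZE, Sketch, build_sketch, jaccard

logger = logging.getLogger("skimdist")

SKETCH_FILE = "sketch.txt.gz"
PROFILE_FILE = "profile.txt"
MANIFEST_FILE = "manifest.json"


def process_skim(
    path: str | Path,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
    is_assembly: bool = False,
    epsilon_override: float | None = None,
    coverage_override: float | None = None,
) -> tuple[Sketch, SkimProfile]:
    """Count -> histogram -> profile -> sketch for one input file.

    The profile's abundance filter m is applied before sketching, so
    high-coverage skims shed their (almost surely erroneous) low-copy
    k-mers while low-coverage skims keep everything.
    """
    stats, seqs = read_sequences(path, is_assembly=is_assembly)
    table = count_kmers(seqs, k)
    hist = histogram(table) if not is_assembly else None
    prof = build_profile(
        hist, stats, k,
        epsilon_override=epsilon_override, coverage_override=coverage_override,
    )
    logger.info(
        "%s: c=%.4g eps=%.4g L=%.6g m=%d regime=%s",
        path, prof.coverage, prof.epsilon, prof.genome_length, prof.m, prof.regime,
    )
    sk = build_sketch(table, s=s, m=prof.m, hash_seed=hash_seed)
    return sk, prof


@dataclass
class ReferenceLibrary:
    root: Path
    names: list[str]
    k: int
    s: int
    hash_seed: int

    def entry_paths(self, name: str) -> tuple[Path, Path]:
        d = self.root / name
        return d / SKETCH_FILE, d / PROFILE_FILE

    def load_entry(self, name: str) -> tuple[Sketch, SkimProfile]:
        sketch_path, profile_path = self.entry_paths(name)
        return Sketch.from_file(sketch_path), SkimProfile.from_file(profile_path)

    def save(self) -> None:
        manifest = dict(names=self.names, k=self.k, s=self.s, hash_seed=self.hash_seed)
        with open(self.root / MANIFEST_FILE, "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def open(cls, root: str | Path) -> "ReferenceLibrary":
        root = Path(root)
        with open(root / MANIFEST_FILE) as fh:
            manifest = json.load(fh)
        return cls(root=root, names=list(manifest["names"]), k=manifest["k"],
                   s=manifest["s"], hash_seed=manifest["hash_seed"])


def build_library(
    skim_paths: Sequence[str | Path],
    out_dir: str | Path,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
    is_assembly: bool = False,
) -> ReferenceLibrary:
    """Process each skim and persist (sketch, profile) under its name.

    Sample names are the file stems; duplicates are an error.  A sample
    whose spectrum cannot support estimation is skipped with a warning so
    one bad file does not sink the library.
    """
    if not skim_paths:
        raise ValueError("need at least one skim")
    names = [Path(p).name.split(".")[0] for p in skim_paths]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sample names: {dupes}")
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    kept: list[str] = []
    for name, path in zip(names, skim_paths):
        try:
            sk, prof = process_skim(path, k=k, s=s, hash_seed=hash_seed,
                                    is_assembly=is_assembly)
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping sample {name!r}: {exc}")
            continue
        d = root / name
        d.mkdir(exist_ok=True)
        sk.to_file(d / SKETCH_FILE)
        prof.to_file(d / PROFILE_FILE)
        kept.append(name)
    if not kept:
        raise ValueError("no sample could be processed")
    lib = ReferenceLibrary(root=root, names=sorted(kept), k=k, s=s, hash_seed=hash_seed)
    lib.save()
    return lib


RankedMatches = list[tuple[str, float]]


def rank_matches(
    query_entry: tuple[Sketch, SkimProfile],
    references: Mapping[str, tuple[Sketch, SkimProfile]],
) -> RankedMatches:
    """Corrected distance to every reference, ascending, ties by name."""
    if not references:
        raise ValueError("empty reference collection")
    q_sketch, q_prof = query_entry
    out = []
    for name, (r_sketch, r_prof) in references.items():
        d = skim_distance(jaccard(q_sketch, r_sketch), q_prof, r_prof).D
        out.append((name, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


def query(
    library: ReferenceLibrary,
    query_path: str | Path,
    is_assembly: bool = False,
    epsilon_override: float | None = None,
    coverage_override: float | None = None,
) -> RankedMatches:
    """Rank every library entry by corrected distance to a query skim."""
    if not library.names:
        raise ValueError("empty library")
    q_entry = process_skim(
        query_path, k=library.k, s=library.s, hash_seed=library.hash_seed,
        is_assembly=is_assembly,
        epsilon_override=epsilon_override, coverage_override=coverage_override,
    )
    refs = {name: library.load_entry(name) for name in library.names}
    return rank_matches(q_entry, refs)


# ---------------------------------------------------------------------------
# leave-out evaluation
# ---------------------------------------------------------------------------

def leave_out_eval(
    truth: Mapping[str, Mapping[str, float]],
    method_order: Mapping[str, RankedMatches],
    d_grid: Iterable[float],
) -> dict[float, tuple[float, float]]:
    """Mean rank error and mean relative distance error of the best match.

    For each query q, ``truth[q]`` maps reference names to ground-truth
    distances (the query itself, if present, at 0).  For each threshold d:
    references at ground-truth distance <= d are removed; among the
    remainder, the method's top-ranked pick sits at ground-truth rank r
    (1 = perfect), contributing r - 1 to the rank error and
    (d_pick - d_best) / d_best to the distance error, where d_best is the
    ground-truth distance of the best remaining reference.  Queries with
    fewer than 2 remaining references are skipped with a warning.
    Returns {d: (mean_rank_error, mean_distance_error)}.
    """
    results: dict[float, tuple[float, float]] = {}
    for d in d_grid:
        rank_errors: list[float] = []
        dist_errors: list[float] = []
        for q, truth_d in truth.items():
            remaining = sorted(
                ((dist, name) for name, dist in truth_d.items() if dist > d),
            )
            if len(remaining) < 2:
                warnings.warn(
                    f"query {q!r}: fewer than 2 references beyond d={d}; skipped"
                )
                continue
            keep = {name for _, name in remaining}
            method_remaining = [
                name for name, _ in method_order[q] if name in keep
            ]
            pick = method_remaining[0]
            truth_names = [name for _, name in remaining]
            r = truth_names.index(pick) + 1
            d_best = remaining[0][0]
            d_pick = truth_d[pick]
            rank_errors.append(r - 1)
            dist_errors.append((d_pick - d_best) / d_best)
        if not rank_errors:
            raise ValueError(f"no evaluable query at d={d}")
        results[float(d)] = (
            sum(rank_errors) / len(rank_errors),
            sum(dist_errors) / len(dist_errors),
        )
    return results
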