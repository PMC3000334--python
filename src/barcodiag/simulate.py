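"""Synthetic barcode libraries with known truth for end-to-end testing.

The generator emulates the structure of a multi-species COI reference
library.  Evolution is simulated under the Kimura two-state-rate (K80)
substitution process — the model whose distances the K2P estimator
recovers — on a star phylogeny of species by default:

* a root barcode is drawn uniformly over ACGT;
* each species ancestor receives Poisson(mean_inter * L / 2) substitution
  events from the root (two independent lineages then sit ~mean_inter
  apart);
* each individual receives Poisson(mean_intra * L / 2) events from its
  species ancestor (a conspecific pair sits ~mean_intra apart);
* each substitution picks a uniform site and mutates it, transitions with
  probability kappa / (kappa + 2), either transversion with probability
  1 / (kappa + 2); multiple hits are allowed, so realised K2P distances
  shrink slightly below the event counts at high divergence;
* optional subspecies ancestors interpose between species ancestor and
  individuals; optional NB-window planting overwrites the diagnostic and
  monomorphic restriction-site windows; optional degradation truncates a
  fraction of records to a 3' fragment (leading gaps), mimicking short
  legacy-amplicon sequences.

No indels are generated: COI barcodes in these moths show no length
variation beyond read truncation.

Defaults mirror the divergences of a well-separated congeneric library:
mean within-species K2P 0.66%, mean between-species 14.02%, 36 species of
5 individuals, 658-bp frame, transition/transversion rate ratio kappa = 2.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import Library, SequenceRecord
from .rflp import MOTIFS, NBWindows

_BASES = "ACGT"
#: K80 transition partner, index-coded (A<->G, C<->T)
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}
#: non-motif window fillers used to plant an absent site (single mismatch)
_ABSENT = {"NlaIII": "CATA", "BamHI": "GGATCA"}


@dataclass
class SimConfig:
    """Parameters of one simulated reference library."""

    n_species: int = 36
    members_per_species: Union[int, Sequence[int]] = 5
    seq_length: int = 658
    kappa: float = 2.0
    mean_intra_divergence: float = 0.0066
    mean_inter_divergence: float = 0.1402
    #: {species_index: (names, sizes, divergence)} subspecies partition
    subspecies_spec: Optional[dict[int, tuple[list[str], list[int], float]]] = None
    #: {species_index: (N_present, B_present)}; None -> windows evolve freely
    nb_site_plan: Optional[dict[int, tuple[bool, bool]]] = None
    #: (fraction truncated, (min_kept_bp, max_kept_bp)); truncation keeps the 3' end
    degradation: tuple[float, tuple[int, int]] = (0.0, (375, 450))
    #: "star" keeps between-species divergences independent and centred on
    #: mean_inter; "yule" evolves species ancestors along a random-join
    #: binary tree rescaled to the same mean pairwise divergence
    topology: str = "star"
    #: engineer the last two species into a paraphyly: species -2 gets a
    #: ~2.9% internal split with species -1's singleton nested inside it
    plant_paraphyly: bool = False
    windows: NBWindows = field(default_factory=NBWindows)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mean_intra_divergence < 0.75):
            raise ValueError("mean_intra_divergence must lie in [0, 0.75)")
        if not (0.0 <= self.mean_inter_divergence < 0.75):
            raise ValueError("mean_inter_divergence must lie in [0, 0.75)")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.topology not in ("star", "yule"):
            raise ValueError("topology must be 'star' or 'yule'")
        self.member_counts  # validate member list length eagerly

    @property
    def member_counts(self) -> list[int]:
        if isinstance(self.members_per_species, int):
            counts = [self.members_per_species] * self.n_species
        else:
            counts = list(self.members_per_species)
            if len(counts) != self.n_species:
                raise ValueError("members_per_species list length != n_species")
        if self.plant_paraphyly:
            if self.n_species < 2:
                raise ValueError("paraphyly planting needs >= 2 species")
            counts[-2] = max(counts[-2], 3)
            counts[-1] = 1
        return counts


@dataclass
class TruthTable:
    """Ground truth for a simulated library."""

    records: pd.DataFrame   # id, species, subspecies, haplotype_id, nb_haplotype, subs_from_ancestor, truncated_to
    species: pd.DataFrame   # species, subs_from_root
    root_sequence: str


def _mutate(seq: np.ndarray, n_events: int, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply K80 substitution events in place-free fashion."""
    out = seq.copy()
    if n_events == 0:
        return out
    sites = rng.integers(0, out.size, size=n_events)
    p_ts = kappa / (kappa + 2.0)
    r = rng.random(n_events)
    for site, u in zip(sites, r):
        base = out[site]
        if u < p_ts:
            out[site] = _TRANSITION[int(base)]
        else:
            # pick one of the two transversion partners
            tv = [b for b in range(4) if b != base and b != _TRANSITION[int(base)]]
            out[site] = tv[0] if u < p_ts + (1.0 - p_ts) / 2.0 else tv[1]
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[int(b)] for b in arr)


def _plant_window(arr: np.ndarray, window: tuple[int, int], text: str) -> None:
    lo, hi = window
    arr[lo - 1:hi] = [_BASES.index(ch) for ch in text]


def _poisson(rng: np.random.Generator, lam: float) -> int:
    return int(rng.poisson(lam))


def _yule_ancestors(root: np.ndarray, n: int, mean_inter: float, kappa: float,
                    rng: np.random.Generator) -> tuple[list[np.ndarray], list[int]]:
    """Species ancestors evolved along a random-join binary tree whose edge
    lengths (exponential draws) are rescaled so the mean leaf-pair path
    distance equals ``mean_inter``."""
    import itertools

    L = root.size
    parent: dict[int, int] = {}
    elen: dict[int, float] = {}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        elen[a] = float(rng.exponential())
        elen[b] = float(rng.exponential())
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root_id = active[0]

    paths = {}
    for leaf in range(n):
        x, chain = leaf, []
        while x != root_id:
            chain.append(x)
            x = parent[x]
        paths[leaf] = set(chain)
    dists = [sum(elen[x] for x in paths[a] ^ paths[b])
             for a, b in itertools.combinations(range(n), 2)]
    scale = mean_inter / (sum(dists) / len(dists))

    seqs = {root_id: root}
    events = {root_id: 0}
    for node in sorted(parent, reverse=True):  # parents were created later
        ev = _poisson(rng, elen[node] * scale * L)
        seqs[node] = _mutate(seqs[parent[node]], ev, kappa, rng)
        events[node] = events[parent[node]] + ev
    return [seqs[leaf] for leaf in range(n)], [events[leaf] for leaf in range(n)]


def simulate_library(cfg: SimConfig) -> tuple[Library, TruthTable]:
    """Generate a reference library and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    root = rng.integers(0, 4, size=L).astype(np.int64)
    counts = cfg.member_counts

    species_names = [f"species_{i + 1:02d}" for i in range(cfg.n_species)]
    sp_rows, rec_rows, records = [], [], []

    if cfg.topology == "yule" and cfg.n_species >= 2:
        ancestors, anc_events = _yule_ancestors(
            root, cfg.n_species, cfg.mean_inter_divergence, cfg.kappa, rng)
    else:
        ancestors, anc_events = [], []
        for i in range(cfg.n_species):
            ev = _poisson(rng, cfg.mean_inter_divergence * L / 2.0)
            ancestors.append(_mutate(root, ev, cfg.kappa, rng))
            anc_events.append(ev)

    para_ancestor = None
    if cfg.plant_paraphyly:
        # species -1 (a singleton) branches from an internal lineage of
        # species -2, splitting species -2 by ~2.9% K2P with the singleton
        # nested on the far side of the split
        split_events = max(1, round(0.029 * L))
        para_ancestor = _mutate(ancestors[-2], split_events, cfg.kappa, rng)

    for i, sp in enumerate(species_names):
        sp_rows.append({"species": sp, "subs_from_root": anc_events[i]})
        subspecies_plan = (cfg.subspecies_spec or {}).get(i)
        sub_ancestors: dict[Optional[str], np.ndarray] = {None: ancestors[i]}
        member_sub: list[Optional[str]] = []
        if subspecies_plan is not None:
            names, sizes, div = subspecies_plan
            if sum(sizes) != counts[i]:
                raise ValueError(f"subspecies sizes for species {i} do not sum to member count")
            for name in names:
                ev = _poisson(rng, div * L / 2.0)
                sub_ancestors[name] = _mutate(ancestors[i], ev, cfg.kappa, rng)
            for name, size in zip(names, sizes):
                member_sub.extend([name] * size)
        else:
            member_sub = [None] * counts[i]

        for m, subname in enumerate(member_sub):
            rid = f"{sp}_{m + 1:03d}"
            base_anc = sub_ancestors[subname]
            if cfg.plant_paraphyly and i == cfg.n_species - 2 and m == 0:
                base_anc = para_ancestor  # one member sits on the far side of the split
            if cfg.plant_paraphyly and i == cfg.n_species - 1:
                # the nested singleton diverges from the same internal lineage
                base_anc = _mutate(para_ancestor, max(1, round(0.0145 * L)), cfg.kappa, rng)
            ev = _poisson(rng, cfg.mean_intra_divergence * L / 2.0)
            seq = _mutate(base_anc, ev, cfg.kappa, rng)

            nb_hap = None
            plan = (cfg.nb_site_plan or {}).get(i)
            if plan is not None:
                n_state, b_state = plan
                w = cfg.windows
                _plant_window(seq, w.monomorphic_n_window, MOTIFS["NlaIII"])
                _plant_window(seq, w.n_window,
                              MOTIFS["NlaIII"] if n_state else _ABSENT["NlaIII"])
                _plant_window(seq, w.b_window,
                              MOTIFS["BamHI"] if b_state else _ABSENT["BamHI"])
                nb_hap = f"N{'+' if n_state else '-'}B{'+' if b_state else '-'}"

            rec_rows.append({"id": rid, "species": sp, "subspecies": subname,
                             "nb_haplotype": nb_hap, "subs_from_ancestor": ev,
                             "sequence_clean": _decode(seq)})
            records.append((rid, sp, subname, seq))

    # haplotype ids from identical clean sequences
    hap_ids: dict[str, int] = {}
    for row in rec_rows:
        hap_ids.setdefault(row["sequence_clean"], len(hap_ids))
    for row in rec_rows:
        row["haplotype_id"] = hap_ids[row["sequence_clean"]]

    # degradation last: truncate a fraction to their 3' end
    frac, (lo, hi) = cfg.degradation
    truncate = rng.random(len(records)) < frac
    kept_len = rng.integers(lo, hi + 1, size=len(records))
    out_records = []
    for idx, (rid, sp, subname, seq) in enumerate(records):
        text = _decode(seq)
        trunc_to = None
        if truncate[idx]:
            trunc_to = int(min(kept_len[idx], L))
            text = "-" * (L - trunc_to) + text[L - trunc_to:]
        rec_rows[idx]["truncated_to"] = trunc_to
        out_records.append(SequenceRecord(id=rid, sequence=text, species=sp,
                                          subspecies=subname, source="synthetic"))

    rec_df = pd.DataFrame(rec_rows).drop(columns=["sequence_clean"])
    truth = TruthTable(records=rec_df, species=pd.DataFrame(sp_rows),
                       root_sequence=_decode(root))
    return Library(out_records), truth


def simulate_nb_amplicon(n_state: bool, b_state: bool, seed: int = 0,
                         windows: Optional[NBWindows] = None) -> str:
    """A barcode-frame sequence whose ONLY restriction motifs are the planted
    NB-system sites: the monomorphic NlaIII site plus the diagnostic N/B
    windows in the requested states.

    Random COI-length sequence carries chance CATG matches (~1 per 256 bp),
    which is faithful to real digests; this builder scrubs them so gel
    band-count arithmetic (two vs three NlaIII bands on the barcode
    amplicon) can be demonstrated in isolation.
    """
    w = windows or NBWindows()
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=w.barcode_length).astype(np.int64)
    _plant_window(seq, w.monomorphic_n_window, MOTIFS["NlaIII"])
    _plant_window(seq, w.n_window, MOTIFS["NlaIII"] if n_state else _ABSENT["NlaIII"])
    _plant_window(seq, w.b_window, MOTIFS["BamHI"] if b_state else _ABSENT["BamHI"])
    planted_starts = {w.monomorphic_n_window[0] - 1}
    if n_state:
        planted_starts.add(w.n_window[0] - 1)
    if b_state:
        planted_starts.add(w.b_window[0] - 1)
    protected = set()
    for lo, hi in (w.monomorphic_n_window, w.n_window, w.b_window):
        protected.update(range(lo - 1, hi))
    text = _decode(seq)
    for _ in range(10 * w.barcode_length):  # bounded scrub loop
        stray = None
        for motif in MOTIFS.values():
            start = text.find(motif)
            while start != -1:
                if start not in planted_starts:
                    hit = next((p for p in range(start, start + len(motif))
                                if p not in protected), None)
                    if hit is not None:
                        stray = hit
                        break
                start = text.find(motif, start + 1)
            if stray is not None:
                break
        if stray is None:
            return text
        old = text[stray]
        new = _BASES[(_BASES.index(old) + 1 + int(rng.integers(3))) % 4]
        text = text[:stray] + new + text[stray + 1:]
    raise RuntimeError("could not scrub stray restriction motifs")


def inject_shared_haplotype(lib: Library, from_species: str, to_species: str) -> Library:
    """Overwrite one member of ``to_species`` with a sequence copied from
    ``from_species``, creating a between-species shared haplotype."""
    donor = next(r for r in lib if r.species == from_species)
    new_records = []
    done = False
    for r in lib:
        if not done and r.species == to_species:
            new_records.append(SequenceRecord(id=r.id, sequence=donor.sequence,
                                              species=r.species, subspecies=r.subspecies,
                                              source=r.source))
            done = True
        else:
            new_records.append(r)
    if not done:
        raise ValueError(f"no records of species {to_species!r}")
    return Library(new_records)


def simulate_queries(
    lib: Library,
    truth: TruthTable,
    n_queries: int,
    mode: str = "held_out",
    seed: int = 0,
    cfg: Optional[SimConfig] = None,
) -> tuple[list[SequenceRecord], Library, pd.DataFrame]:
    """Draw surveillance-style query sequences with an answer key.

    ``held_out`` removes existing members from a library copy (never
    depleting a species below one remaining reference, so every query
    retains conspecific references); ``novel_species`` evolves queries from
    an ancestor absent from the library (requires ``cfg`` for the
    divergence parameters).  Returns (queries, remaining_library, key).
    """
    rng = np.random.default_rng(seed)
    if mode == "held_out":
        remaining = {r.id: r for r in lib}
        by_species: dict[str, list[str]] = {}
        for r in lib:
            by_species.setdefault(r.species, []).append(r.id)
        chosen: list[str] = []
        order = list(remaining)
        for _ in range(n_queries):
            pool = [rid for rid in order if rid in remaining
                    and len(by_species[remaining[rid].species]) > 1]
            if not pool:
                raise ValueError("not enough removable records for held_out queries")
            rid = pool[int(rng.integers(len(pool)))]
            rec = remaining.pop(rid)
            by_species[rec.species].remove(rid)
            chosen.append(rid)
        queries = [next(r for r in lib if r.id == rid) for rid in chosen]
        queries = [SequenceRecord(id=f"query_{q.id}", sequence=q.sequence,
                                  species=q.species, subspecies=q.subspecies,
                                  source="surveillance") for q in queries]
        key = pd.DataFrame({
            "query_id": [q.id for q in queries],
            "true_species": [q.species for q in queries],
            "true_subspecies": [q.subspecies for q in queries],
        })
        return queries, Library(list(remaining.values())), key

    if mode == "novel_species":
        if cfg is None:
            raise ValueError("novel_species mode requires the SimConfig")
        L = cfg.seq_length
        root = np.array([_BASES.index(ch) for ch in truth.root_sequence])
        anc = _mutate(root, _poisson(rng, cfg.mean_inter_divergence * L / 2.0),
                      cfg.kappa, rng)
        queries = []
        for i in range(n_queries):
            seq = _mutate(anc, _poisson(rng, cfg.mean_intra_divergence * L / 2.0),
                          cfg.kappa, rng)
            queries.append(SequenceRecord(id=f"novel_{i + 1:03d}", sequence=_decode(seq),
                                          species="novel", source="surveillance"))
        key = pd.DataFrame({"query_id": [q.id for q in queries],
                            "true_species": ["novel"] * n_queries,
                            "true_subspecies": [None] * n_queries})
        return queries, lib, key

    raise ValueError("mode must be 'held_out' or 'novel_species'")
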