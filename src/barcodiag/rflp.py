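"""In-silico 'NB system' restriction typing of COI barcodes.

The legacy gypsy-moth diagnostic digests a ~378-bp COI amplicon with two
enzymes, NlaIII (CATG, cuts after position 4: CATG^) and BamHI (GGATCC,
cuts after position 1: G^GATCC).  Presence (+) or absence (-) of each
diagnostic site yields four haplotypes, keyed by fragment size:

    NlaIII ~350 bp / BamHI ~400 bp  ->  N+ B-
    NlaIII ~350 bp / BamHI ~360 bp  ->  N+ B+
    NlaIII ~400 bp / BamHI ~400 bp  ->  N- B-
    NlaIII ~400 bp / BamHI ~360 bp  ->  N- B+

(the ~400-bp "fragment" is the undigested amplicon).  The 658-bp barcode
region covers 360 bp of that amplicon, including both diagnostic sites, and
additionally carries a monomorphic NlaIII site near its 5' end, so an
NlaIII digest of the barcode amplicon gives three bands (N+) or two (N-)
instead of two/one.

The precise diagnostic coordinates are configuration
(:class:`NBWindows`); the shipped defaults place the sites so the classic
fragment arithmetic above is reproduced exactly.  The 18 bp of the legacy
amplicon upstream of the barcode frame are not recoverable from barcode
data, so legacy digests are simulated on a synthetic amplicon: a fixed
18-bp synthetic primer-side pad followed by the barcode's 3' 360 bp.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .seqio import Library, collapse_haplotypes

logger = logging.getLogger(__name__)

MOTIFS = {"NlaIII": "CATG", "BamHI": "GGATCC"}
#: cut offset within the motif: NlaIII CATG^ (3' overhang), BamHI G^GATCC
CUT_OFFSETS = {"NlaIII": 4, "BamHI": 1}

UNDETERMINABLE = "undeterminable"

#: synthetic primer-side pad completing the legacy amplicon 5' of the
#: barcode frame (18 bp; arbitrary motif-free sequence, NOT the historical
#: primer region)
LEGACY_PAD_5PRIME = "TTAACTTCAGCCATCTTA"


@dataclass(frozen=True)
class EnzymeSite:
    enzyme: str
    position: int  # 1-based motif start on the (gap-stripped) sequence
    role: str      # diagnostic_N | diagnostic_B | monomorphic | other


@dataclass(frozen=True)
class NBWindows:
    """1-based inclusive coordinates of the NB-system sites on the 658-bp
    barcode frame, plus the geometry linking barcode and legacy amplicon."""

    n_window: tuple[int, int] = (629, 632)        # diagnostic NlaIII CATG
    b_window: tuple[int, int] = (639, 644)        # diagnostic BamHI GGATCC
    monomorphic_n_window: tuple[int, int] = (112, 115)  # 5' NlaIII CATG
    barcode_length: int = 658
    legacy_overlap_start: int = 299  # barcode position where the legacy amplicon's overlap begins

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# NB-system site coordinates, 1-based inclusive, on the barcode frame\n")
            fh.write(f"n_window = [{self.n_window[0]}, {self.n_window[1]}]\n")
            fh.write(f"b_window = [{self.b_window[0]}, {self.b_window[1]}]\n")
            fh.write("monomorphic_n_window = "
                     f"[{self.monomorphic_n_window[0]}, {self.monomorphic_n_window[1]}]\n")
            fh.write(f"barcode_length = {self.barcode_length}\n")
            fh.write(f"legacy_overlap_start = {self.legacy_overlap_start}\n")

    @staticmethod
    def from_toml(path) -> "NBWindows":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        return NBWindows(
            n_window=tuple(cfg["n_window"]),
            b_window=tuple(cfg["b_window"]),
            monomorphic_n_window=tuple(cfg["monomorphic_n_window"]),
            barcode_length=cfg.get("barcode_length", 658),
            legacy_overlap_start=cfg.get("legacy_overlap_start", 299),
        )


DEFAULT_WINDOWS = NBWindows()


@dataclass
class NBProfile:
    id: str
    N_present: Optional[bool]  # None = undeterminable
    B_present: Optional[bool]
    haplotype: str             # N+B+ | N+B- | N-B+ | N-B- | undeterminable
    fragments_legacy: Optional[dict[str, list[int]]] = None
    fragments_barcode: Optional[dict[str, list[int]]] = None


def _strip_gaps(seq: str) -> str:
    return seq.replace("-", "")


def _window_state(seq: str, window: tuple[int, int], motif: str) -> Optional[bool]:
    """True/False for motif presence at the window; None when undeterminable."""
    lo, hi = window
    if hi - lo + 1 != len(motif):
        raise ValueError(f"window {window} does not fit motif {motif}")
    if len(seq) < hi:
        return None
    sub = seq[lo - 1:hi]
    if any(ch not in "ACGT" for ch in sub):
        return None
    return sub == motif


def scan_sites(seq: str, windows: NBWindows = DEFAULT_WINDOWS
               ) -> tuple[list[EnzymeSite], list[str]]:
    """All exact enzyme-motif matches with NB-system roles.

    Returns ``(hits, undeterminable_windows)``; a window the sequence does
    not fully cover is reported undeterminable rather than absent.
    """
    s = _strip_gaps(seq.upper())
    role_windows = {
        "diagnostic_N": ("NlaIII", windows.n_window),
        "diagnostic_B": ("BamHI", windows.b_window),
        "monomorphic": ("NlaIII", windows.monomorphic_n_window),
    }
    hits: list[EnzymeSite] = []
    for enzyme, motif in MOTIFS.items():
        start = s.find(motif)
        while start != -1:
            pos = start + 1
            role = "other"
            for rname, (renz, win) in role_windows.items():
                if renz == enzyme and pos == win[0]:
                    role = rname
            hits.append(EnzymeSite(enzyme, pos, role))
            start = s.find(motif, start + 1)
    undet = [rname for rname, (renz, win) in role_windows.items()
             if len(s) < win[1]]
    return hits, undet


def digest_fragments(amplicon_seq: str, enzymes: Sequence[str]) -> list[int]:
    """Fragment lengths (bp, descending) after digesting with ``enzymes``.

    Cuts at every motif occurrence at the enzyme's cut offset; fragment
    lengths always sum to the amplicon length.
    """
    s = _strip_gaps(amplicon_seq.upper())
    L = len(s)
    cuts: set[int] = set()
    for enzyme in enzymes:
        motif, off = MOTIFS[enzyme], CUT_OFFSETS[enzyme]
        start = s.find(motif)
        while start != -1:
            cut = start + off
            if 0 < cut < L:
                cuts.add(cut)
            start = s.find(motif, start + 1)
    bounds = [0] + sorted(cuts) + [L]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(frags, reverse=True)


def legacy_amplicon(barcode_seq: str, windows: NBWindows = DEFAULT_WINDOWS) -> str:
    """Synthetic ~378-bp legacy amplicon: 18-bp synthetic pad + barcode 3' 360 bp."""
    s = _strip_gaps(barcode_seq.upper())
    if len(s) < windows.barcode_length:
        raise ValueError("barcode sequence does not cover the full frame")
    return LEGACY_PAD_5PRIME + s[windows.legacy_overlap_start - 1:windows.barcode_length]


def nb_type(seq: str, seq_id: str = "", windows: NBWindows = DEFAULT_WINDOWS,
            with_fragments: bool = True) -> NBProfile:
    """NB haplotype of a barcode sequence from its diagnostic windows.

    A window covered by gaps/N or truncated away yields an undeterminable
    haplotype, which is distinct from N-/B- (absence requires an
    unambiguous non-motif state).
    """
    s = _strip_gaps(seq.upper())
    n_state = _window_state(s, windows.n_window, MOTIFS["NlaIII"])
    b_state = _window_state(s, windows.b_window, MOTIFS["BamHI"])
    if n_state is None or b_state is None:
        logger.warning("record %s: NB haplotype undeterminable", seq_id or "<anon>")
        return NBProfile(seq_id, n_state, b_state, UNDETERMINABLE)
    hap = f"N{'+' if n_state else '-'}B{'+' if b_state else '-'}"
    prof = NBProfile(seq_id, n_state, b_state, hap)
    if with_fragments and len(s) >= windows.barcode_length:
        amp = legacy_amplicon(s, windows)
        prof.fragments_legacy = {e: digest_fragments(amp, [e]) for e in MOTIFS}
        prof.fragments_barcode = {e: digest_fragments(s[:windows.barcode_length], [e])
                                  for e in MOTIFS}
    return prof


def nb_type_library(lib: Library, windows: NBWindows = DEFAULT_WINDOWS) -> pd.DataFrame:
    rows = []
    for rec in lib:
        prof = nb_type(rec.sequence, rec.id, windows, with_fragments=False)
        rows.append({"id": rec.id, "species": rec.species,
                     "subspecies": rec.subspecies,
                     "nb_haplotype": prof.haplotype})
    return pd.DataFrame(rows)


@dataclass
class NBComparison:
    per_species: pd.DataFrame   # species, nb_haplotypes (sorted join), n_records
    class_summary: pd.DataFrame # nb_class, n_species, n_barcode_haplotypes
    collisions: pd.DataFrame    # nb_class, species list sharing it
    barcode_haplotypes_species_unique: bool


def nb_vs_barcode_report(lib: Library, windows: NBWindows = DEFAULT_WINDOWS,
                         min_overlap: int = 300) -> NBComparison:
    """Contrast the 4-state NB typing with full barcode haplotypes.

    Flags NB classes shared by more than one species (the misdiagnosis
    hazard of the legacy assay) and reports whether barcode haplotypes are
    species-unique in this library.
    """
    typed = nb_type_library(lib, windows)
    haps, _ = collapse_haplotypes(lib, min_overlap=min_overlap)
    hap_of: dict[str, int] = {}
    hap_class: dict[int, str] = {}
    nb_of = dict(zip(typed["id"], typed["nb_haplotype"]))
    for hid, h in enumerate(haps):
        for mid in h.member_ids:
            hap_of[mid] = hid
        classes = {nb_of[mid] for mid in h.member_ids}
        hap_class[hid] = classes.pop() if len(classes) == 1 else "mixed"

    per_species = (
        typed.groupby("species")
        .agg(nb_haplotypes=("nb_haplotype", lambda s: ",".join(sorted(set(s)))),
             n_records=("id", "size"))
        .reset_index()
    )

    rows = []
    determinate = typed[typed["nb_haplotype"] != UNDETERMINABLE]
    for nb_class, grp in determinate.groupby("nb_haplotype"):
        n_species = grp["species"].nunique()
        hids = {hap_of[i] for i in grp["id"] if i in hap_of}
        rows.append({"nb_class": nb_class, "n_species": n_species,
                     "n_barcode_haplotypes": len(hids)})
    class_summary = pd.DataFrame(rows)

    coll_rows = [
        {"nb_class": r["nb_class"],
         "species": sorted(determinate[determinate["nb_haplotype"] == r["nb_class"]]
                           ["species"].unique())}
        for _, r in class_summary.iterrows() if r["n_species"] > 1
    ]
    collisions = pd.DataFrame(coll_rows, columns=["nb_class", "species"])
    unique = all(not h.shared_between_species for h in haps)
    return NBComparison(per_species, class_summary, collisions, unique)
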