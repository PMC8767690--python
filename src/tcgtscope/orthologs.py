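"""Cross-species TE locus conservation and KZFP zinc-fingerprint similarity.

TE side: a human locus is scored against each foreign genome by the number
of its bases covered by the pairwise alignment of the syntenic (lifted)
locus, normalized by the subfamily consensus length (so short integrants do
not look artificially conserved), and classified by whether the foreign
annotation names the same subfamily, the same family, or nothing.

KZFP side: the zinc fingerprint is the ordered list of the four
DNA-contacting residues (positions -1, 2, 3 and 6) of each zinc finger.
Two fingerprints are compared by global alignment of their finger
sequences: matching a pair of fingers scores the fraction of identical
residues (0..1 in steps of 1/4), skipping a finger costs 0.25, and the
optimal total is normalized by the longer fingerprint.  This scoring rule
is this package's own declared convention, not a canonical one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")
GAP_PENALTY = 0.25


class OrthologStatus(str, Enum):
    NOT_DETECTED = "not_detected"
    SAME_SUBFAMILY = "detected_same_subfamily"
    SAME_FAMILY = "detected_same_family"
    UNANNOTATED = "detected_unannotated"


@dataclass
class OrthologHit:
    human_locus_id: str
    species: str
    status: OrthologStatus
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 1.0):
            raise ValueError(f"similarity outside [0,1]: {self.similarity}")
        if (self.status is OrthologStatus.NOT_DETECTED) != (self.similarity == 0.0):
            raise ValueError(
                f"{self.human_locus_id}/{self.species}: similarity must be 0 "
                f"exactly when status is not_detected (got {self.status.value}, {self.similarity})"
            )


@dataclass
class Fingerprint:
    kzfp_id: str
    fingers: list[str]

    def __post_init__(self) -> None:
        if not self.fingers:
            raise ValueError(f"{self.kzfp_id}: fingerprint without fingers")
        for f in self.fingers:
            if len(f) != 4 or any(c not in _AA for c in f):
                raise ValueError(f"{self.kzfp_id}: malformed finger {f!r}")


def alignment_coverage_score(human_len: int, aligned_bp: int, consensus_len: int) -> float:
    """Aligned human bases normalized by the subfamily consensus length, capped at 1."""
    if consensus_len <= 0:
        raise ValueError(f"consensus_len must be positive, got {consensus_len}")
    if not (0 <= aligned_bp <= human_len):
        raise ValueError(f"need 0 <= aligned_bp <= human_len, got {aligned_bp}/{human_len}")
    return min(1.0, aligned_bp / consensus_len)


def classify_ortholog(
    lifted: bool,
    annotation: str | None,
    human_subfamily: str,
    family_map: Mapping[str, str],
) -> OrthologStatus:
    """Classify a syntenic locus by its foreign repeat annotation."""
    if human_subfamily not in family_map:
        raise KeyError(f"human subfamily {human_subfamily!r} absent from family map")
    if not lifted:
        return OrthologStatus.NOT_DETECTED
    if annotation is None or annotation == "":
        return OrthologStatus.UNANNOTATED
    if annotation == human_subfamily:
        return OrthologStatus.SAME_SUBFAMILY
    if family_map.get(annotation) == family_map[human_subfamily]:
        return OrthologStatus.SAME_FAMILY
    return OrthologStatus.UNANNOTATED


def _finger_match(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / 4.0


def fingerprint_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Global-alignment similarity of two zinc fingerprints in [0,1].

    Dynamic programming over finger sequences maximizing the summed
    per-finger identity fraction, with a 0.25 penalty per skipped finger;
    the optimum is divided by max(len(a), len(b)) and clamped to [0,1].
    """
    na, nb = len(a.fingers), len(b.fingers)
    dp = np.empty((na + 1, nb + 1))
    dp[0, :] = -GAP_PENALTY * np.arange(nb + 1)
    dp[:, 0] = -GAP_PENALTY * np.arange(na + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + _finger_match(a.fingers[i - 1], b.fingers[j - 1]),
                dp[i - 1, j] - GAP_PENALTY,
                dp[i, j - 1] - GAP_PENALTY,
            )
    return float(np.clip(dp[na, nb] / max(na, nb), 0.0, 1.0))


def best_ortholog(query: Fingerprint, candidates: Sequence[Fingerprint]) -> tuple[str, float]:
    """Highest-scoring candidate; ties break to the smallest kzfp_id (flagged)."""
    if not candidates:
        raise ValueError("empty candidate list")
    scores = {c.kzfp_id: fingerprint_similarity(query, c) for c in candidates}
    best_score = max(scores.values())
    winners = sorted(k for k, v in scores.items() if v == best_score)
    if len(winners) > 1:
        log.info("best_ortholog: tie at %.4f among %s; picking %s", best_score, winners, winners[0])
    return winners[0], best_score


def score_synteny_table(
    synteny: pd.DataFrame,
    consensus_lengths: Mapping[str, int],
    subfamily_of: Mapping[str, str],
    family_map: Mapping[str, str],
) -> list[OrthologHit]:
    """Score a (human_locus, species) synteny table into OrthologHits.

    ``synteny`` columns: human_locus_id, species, lifted (bool/int),
    foreign_label (empty or '.' for unannotated), aligned_bp, human_len.
    """
    hits = []
    for row in synteny.itertuples(index=False):
        subfam = subfamily_of[row.human_locus_id]
        lifted = bool(row.lifted)
        label = None if row.foreign_label in (None, "", ".") or pd.isna(row.foreign_label) else str(row.foreign_label)
        status = classify_ortholog(lifted, label, subfam, family_map)
        sim = 0.0
        if lifted:
            sim = alignment_coverage_score(int(row.human_len), int(row.aligned_bp), consensus_lengths[subfam])
        hits.append(OrthologHit(row.human_locus_id, row.species, status, sim))
    return hits


def hits_to_frame(hits: Sequence[OrthologHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"human_locus_id": h.human_locus_id, "species": h.species,
          "status": h.status.value, "similarity": h.similarity} for h in hits]
    )


def read_fingerprints(path) -> dict[str, Fingerprint]:
    """Read a fingerprint TSV (kzfp_id, finger_index, residues)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for kid, grp in df.groupby("kzfp_id", sort=True):
        fingers = grp.sort_values("finger_index")["residues"].tolist()
        out[kid] = Fingerprint(kid, fingers)
    return out


def write_fingerprints(fps: Mapping[str, Fingerprint], path) -> None:
    rows = [
        {"kzfp_id": f.kzfp_id, "finger_index": i, "residues": res}
        for f in fps.values()
        for i, res in enumerate(f.fingers)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
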