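"""Ensembling: median aggregation and the two member-selection rules.

*Objective 1* (smallest MAE): five fixed model recipes differing in input
channels, regularization and covariates, each contributing its best (smallest
validation MAE) checkpoint; predictions are combined by the per-subject
median.

*Objective 2* (smallest MAE while keeping the brain-age-delta bias low):
every per-epoch checkpoint of every configuration is a candidate.  Candidates
are filtered to validation MAE below 3.8 years and |Spearman rho| of delta vs
age below 0.1, ranked by MAE (ties by |rho|, then configuration id and
epoch), and the top eight survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.train import CheckpointRecord

MAE_MAX = 3.8  # years
RHO_MAX = 0.1
TOP_K = 8


@dataclass
class MemberRecipe:
    """One ensemble member: its input channels and training variations."""

    name: str
    channels: tuple[str, ...]
    loss_mode: str = "plain"
    sex_input: bool = False


@dataclass
class EnsembleSet:
    members: list[MemberRecipe]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")


#: The five Objective-1 configurations: channel counts (3, 3, 3, 3, 4).
OBJECTIVE1_RECIPES = (
    MemberRecipe("model1-1", ("t1", "gmv", "wmv")),
    MemberRecipe("model1-2", ("t1", "gmv", "wmv"), loss_mode="rank_reg"),
    MemberRecipe("model1-3", ("t1", "gmv", "wmv"), sex_input=True),
    MemberRecipe("model1-4", ("t1", "gmd", "wmd")),
    MemberRecipe("model1-5", ("t1", "gmd", "wmd", "flair_stub")),
)


def median_aggregate(pred_matrix: np.ndarray) -> np.ndarray:
    """Per-subject median over model rows (models x subjects).

    With an even member count the two central order statistics are averaged.
    """
    pred_matrix = np.asarray(pred_matrix, dtype=float)
    if pred_matrix.ndim != 2 or pred_matrix.shape[0] < 1:
        raise ValueError("pred_matrix must be a (models x subjects) matrix")
    if not np.all(np.isfinite(pred_matrix)):
        raise ValueError("pred_matrix contains missing or non-finite entries")
    return np.median(pred_matrix, axis=0)


def objective1_members(available_channels: set[str] | None = None) -> EnsembleSet:
    """The five fixed Objective-1 recipes, validated against available channels."""
    if available_channels is not None:
        for recipe in OBJECTIVE1_RECIPES:
            missing = [c for c in recipe.channels if c not in available_channels]
            if missing:
                raise KeyError(
                    f"member {recipe.name!r} requires missing channels {missing}"
                )
    return EnsembleSet(members=list(OBJECTIVE1_RECIPES))


def select_checkpoints_objective2(
    records: list[CheckpointRecord],
    mae_max: float = MAE_MAX,
    rho_max: float = RHO_MAX,
    top_k: int = TOP_K,
) -> list[CheckpointRecord]:
    """Filter and rank checkpoints under the low-bias objective.

    Keeps records with ``val_mae < mae_max`` and ``|val_rho| < rho_max``,
    sorts ascending by MAE with deterministic tie-breaks (|rho|, then
    config_id, then epoch), and returns the first ``top_k`` (all qualifiers if
    fewer).  An empty selection is returned with a warning rather than raised:
    the caller decides whether to relax thresholds.
    """
    if not records:
        raise ValueError("no checkpoint records to select from")
    qualifiers = [
        r for r in records if r.val_mae < mae_max and abs(r.val_rho) < rho_max
    ]
    if not qualifiers:
        warnings.warn(
            f"no checkpoint satisfies MAE < {mae_max} and |rho| < {rho_max}",
            stacklevel=2,
        )
        return []
    qualifiers.sort(key=lambda r: (r.val_mae, abs(r.val_rho), r.config_id, r.epoch))
    return qualifiers[:top_k]
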