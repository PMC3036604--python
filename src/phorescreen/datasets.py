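"""Packaged data: the 9-molecule × 11-scoring-function pose-score matrix and
its companion consensus-predicted activities for the screened NCI hits."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import ScoreMatrix, load_score_matrix

__all__ = ["nsc_pose_scores", "nsc_pic50"]


def _data_path(name: str):
    return resources.files("phorescreen.data").joinpath(name)


def nsc_pose_scores() -> ScoreMatrix:
    """The packaged 9 × 11 docking pose-score matrix (all columns oriented
    higher-is-better; the -PLP/-PMF columns are already sign-flipped)."""
    with resources.as_file(_data_path("nsc_pose_scores.csv")) as path:
        return load_score_matrix(path)


def nsc_pic50() -> dict[str, float]:
    """Consensus-predicted pIC50 companion values for the nine molecules."""
    with resources.as_file(_data_path("nsc_pic50.csv")) as path:
        df = pd.read_csv(path)
    return dict(zip(df["id"].astype(str), df["pic50"].astype(float)))
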