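"""Neural representational similarity (NRS) analysis.

For one network layer, the mean activation of every unit is computed for
each of the 380 problems over its test variants, giving a 380 x U mean
response matrix in the canonical problem order (additions before
subtractions, ascending result, ascending first operand). The pairwise
Pearson correlation of rows (across units) forms the 380 x 380 NRS
matrix; block averages summarize addition-subtraction, addition-addition
and subtraction-subtraction similarity, with within-operation blocks
excluding the self-similarity diagonal.

The model-to-brain comparison takes per-subject empirical similarity
values reported on the Fisher-z scale, maps them back to correlation
units with tanh, and correlates them with the model-side values; a
shuffled-pairing baseline quantifies chance alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimuli import OP_ADD, N_RESULTS

N_PROBLEMS = 380


@dataclass
class MeanResponseMatrix:
    layer: str
    values: np.ndarray  # (380, U)
    problems: list  # canonical order


@dataclass
class NRSMatrix:
    layer: str
    values: np.ndarray  # (380, 380), nan marks undefined entries
    problems: list


def mean_response_matrix(activations: np.ndarray, problem_index: np.ndarray,
                         problems: list, layer: str = "") -> MeanResponseMatrix:
    """Per-problem mean activation over test variants, rows canonical.

    ``activations`` is (n_stimuli, U); ``problem_index`` maps each
    stimulus to its index in the canonical problem list.
    """
    activations = np.asarray(activations)
    problem_index = np.asarray(problem_index)
    if len(problems) != N_PROBLEMS:
        raise ValueError(f"expected {N_PROBLEMS} problems, got {len(problems)}")
    out = np.empty((N_PROBLEMS, activations.shape[1]), dtype=np.float64)
    for pi in range(N_PROBLEMS):
        sel = problem_index == pi
        if not sel.any():
            raise ValueError(f"no test variants recorded for problem {problems[pi]}")
        out[pi] = activations[sel].mean(axis=0)
    return MeanResponseMatrix(layer, out, list(problems))


def similarity_matrix(meanresp: MeanResponseMatrix) -> NRSMatrix:
    """Pairwise Pearson correlation of mean-response rows across units.

    Zero-variance rows yield undefined correlations and are flagged with
    nan entries (a warning reports the count).
    """
    x = meanresp.values
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance rows; entries set to nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(x)
    m[dead, :] = np.nan
    m[:, dead] = np.nan
    np.fill_diagonal(m, np.where(dead, np.nan, 1.0))
    return NRSMatrix(meanresp.layer, m, meanresp.problems)


def block_nrs(nrs: NRSMatrix) -> dict:
    """Mean similarity within and across operations.

    add_sub averages all addition x subtraction pairs; add_add and
    sub_sub average unordered distinct within-operation pairs (diagonal
    excluded). Undefined (nan) entries are dropped.
    """
    m = nrs.values
    is_add = np.array([p.operator == OP_ADD for p in nrs.problems])
    a, s = np.nonzero(is_add)[0], np.nonzero(~is_add)[0]

    def off_diag_mean(block):
        v = block[np.triu_indices(block.shape[0], k=1)]
        return float(np.nanmean(v))

    return {
        "add_sub": float(np.nanmean(m[np.ix_(a, s)])),
        "add_add": off_diag_mean(m[np.ix_(a, a)]),
        "sub_sub": off_diag_mean(m[np.ix_(s, s)]),
    }


def layer_nrs_blocks(acts: dict, problem_index: np.ndarray, problems: list) -> dict:
    """Block NRS per layer from a forward_collect activation dict."""
    out = {}
    for layer, a in acts.items():
        mr = mean_response_matrix(a, problem_index, problems, layer)
        out[layer] = block_nrs(similarity_matrix(mr))
    return out


@dataclass
class FisherComparison:
    model: np.ndarray
    fmri_r: np.ndarray  # tanh-transformed empirical values
    r: float
    p: float
    null_r: np.ndarray  # shuffled-pairing baseline


def fisher_compare(model_nrs, fmri_z, n_shuffles: int = 1000, seed: int = 0) -> FisherComparison:
    """Correlate model add-sub NRS with empirical Fisher-z values.

    The empirical values are mapped back to correlation units with the
    inverse Fisher transform (tanh) before computing the Pearson
    correlation; a shuffled-pairing null distribution is returned.
    """
    model_nrs = np.asarray(model_nrs, dtype=float)
    fmri_z = np.asarray(fmri_z, dtype=float)
    if model_nrs.shape != fmri_z.shape:
        raise ValueError("model and fMRI values must be paired one-to-one")
    emp = np.tanh(fmri_z)
    r, p = stats.pearsonr(model_nrs, emp)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = stats.pearsonr(model_nrs, rng.permutation(emp))[0]
    return FisherComparison(model_nrs, emp, float(r), float(p), null)
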