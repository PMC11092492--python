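"""Behavioral response analytics: trueness, precision and granularity.

Given per-stimulus integer responses (0..18) and the expected results,
three summary statistics characterize a responder:

* systematic error (lack of trueness) -- the mean over expected-result
  levels of |mean response - expected result|;
* imprecision -- the mean over expected-result levels of the standard
  deviation of responses at that level;
* effective number of responses -- exp of the Shannon entropy (natural
  log) of the marginal response distribution, ranging from 1 (a single
  response used) to 19 (uniform use of all responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import N_RESULTS


@dataclass
class ResponseProfile:
    mean: np.ndarray  # (19,) mean response per expected result; nan if absent
    sd: np.ndarray  # (19,) population SD per expected result; nan if absent
    count: np.ndarray  # (19,) number of items per expected result
    distribution: np.ndarray  # (19,) marginal distribution of emitted responses


def response_profile(responses, expected) -> ResponseProfile:
    responses = np.asarray(responses, dtype=np.int64)
    expected = np.asarray(expected, dtype=np.int64)
    if responses.shape != expected.shape:
        raise ValueError("responses and expected must have equal length")
    for name, arr in (("responses", responses), ("expected", expected)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_RESULTS):
            raise ValueError(f"{name} outside 0..18")
    mean = np.full(N_RESULTS, np.nan)
    sd = np.full(N_RESULTS, np.nan)
    count = np.zeros(N_RESULTS, dtype=np.int64)
    for r in range(N_RESULTS):
        sel = responses[expected == r]
        count[r] = len(sel)
        if len(sel):
            mean[r] = sel.mean()
            sd[r] = sel.std()  # population SD
    dist = np.bincount(responses, minlength=N_RESULTS).astype(float)
    dist /= max(1, len(responses))
    return ResponseProfile(mean, sd, count, dist)


def _require_all_levels(profile: ResponseProfile):
    missing = np.nonzero(profile.count == 0)[0]
    if len(missing):
        raise ValueError(f"no items for expected result level(s) {missing.tolist()}")


def systematic_error(profile: ResponseProfile) -> float:
    """Mean over result levels of |mean response - expected result|."""
    _require_all_levels(profile)
    return float(np.mean(np.abs(profile.mean - np.arange(N_RESULTS))))


def imprecision(profile: ResponseProfile) -> float:
    """Mean over result levels of the response standard deviation."""
    _require_all_levels(profile)
    return float(np.mean(profile.sd))


def effective_responses(profile: ResponseProfile) -> float:
    """exp(entropy) of the marginal response distribution, in [1, 19]."""
    p = profile.distribution
    p = p[p > 0]
    return float(np.exp(-np.sum(p * np.log(p))))


def behavior_summary(responses, expected) -> dict:
    """All three metrics plus accuracy, from raw response vectors."""
    prof = response_profile(responses, expected)
    return {
        "systematic_error": systematic_error(prof),
        "imprecision": imprecision(prof),
        "effective_responses": effective_responses(prof),
        "accuracy": float(np.mean(np.asarray(responses) == np.asarray(expected))),
    }
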