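"""Multi-rater consensus labelling.

Three examiners independently judge whether a CM/DIF response is present.
A recording is accepted as a response only by unanimity: a unanimous first
round accepts immediately; a 2-of-3 positive first round triggers a second,
blinded presentation whose verdict must again be unanimous; one or zero
positives reject without a second round.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["consensus_label", "consensus_table"]


def consensus_label(
    first_round: Sequence[bool],
    second_round: Sequence[bool] | None = None,
) -> tuple[bool | None, bool]:
    """Apply the unanimity consensus rule to one recording's labels.

    Parameters
    ----------
    first_round : sequence of 3 bool
        The three raters' first-round judgements (order irrelevant).
    second_round : sequence of 3 bool, optional
        Second-round judgements; must be supplied iff the first round was a
        2-of-3 positive split.

    Returns
    -------
    (final, needs_second_round)
        ``final`` is True/False once decidable, or None when a second round
        is required but not yet supplied.
    """
    first_round = [bool(b) for b in first_round]
    if len(first_round) != 3:
        raise ValueError(f"need exactly 3 first-round labels, got {len(first_round)}")
    n_pos = sum(first_round)
    needs_second = n_pos == 2
    if not needs_second:
        if second_round is not None:
            raise ValueError(
                "second-round labels supplied but the first round was decisive"
            )
        return n_pos == 3, False
    if second_round is None:
        return None, True
    second_round = [bool(b) for b in second_round]
    if len(second_round) != 3:
        raise ValueError(f"need exactly 3 second-round labels, got {len(second_round)}")
    return all(second_round), True


def consensus_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Consensus decision per recording from a long-format label table.

    Expects columns ``recording_id, rater_id, round, response_present`` with
    three raters in round 1 and, where required, three in round 2.  Returns a
    frame indexed by ``recording_id`` with columns ``final`` (bool or NaN if
    undecidable) and ``needs_second_round``.
    """
    out = {}
    for rid, grp in labels.groupby("recording_id"):
        r1 = grp.loc[grp["round"] == 1, "response_present"].tolist()
        r2 = grp.loc[grp["round"] == 2, "response_present"].tolist() or None
        if r2 is not None and sum(map(bool, r1)) != 2:
            # tolerate spurious round-2 rows only by rejecting loudly
            raise ValueError(f"recording {rid}: round 2 present without a 2-of-3 split")
        final, needs2 = consensus_label(r1, r2)
        out[rid] = (final, needs2)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["final", "needs_second_round"])
    df.index.name = "recording_id"
    return df
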