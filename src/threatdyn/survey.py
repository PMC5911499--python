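"""Survey-derived predictors: indicator-use score and knowledge score.

The indicator score is the ratio ``(n_correct + 1) / (n_incorrect + 1)``
over the security-indicator identification items; with the default option
counts (3 correct options, 4 incorrect options) it ranges from 0.2 to 4.0.
The knowledge score is the fraction correct on a 10-item quiz, so it lives
on the 0.1 grid in [0, 1].
"""

from __future__ import annotations

from collections.abc import Sequence

from .errors import ValidationError

#: Number of correct / incorrect indicator options offered in the survey.
N_CORRECT_OPTIONS = 3
N_INCORRECT_OPTIONS = 4

#: Number of items on the knowledge quiz.
N_KNOWLEDGE_ITEMS = 10


def score_indicators(
    n_correct: int,
    n_incorrect: int,
    *,
    max_correct: int = N_CORRECT_OPTIONS,
    max_incorrect: int = N_INCORRECT_OPTIONS,
) -> float:
    """Indicator-use score ``(n_correct + 1) / (n_incorrect + 1)``.

    Parameters
    ----------
    n_correct, n_incorrect
        Counts of correctly and incorrectly identified indicators.
    max_correct, max_incorrect
        Number of options of each kind on the survey form; counts outside
        ``[0, max]`` raise :class:`~threatdyn.errors.ValidationError`.
    """
    if not (0 <= n_correct <= max_correct):
        raise ValidationError(
            f"n_correct={n_correct} outside [0, {max_correct}]"
        )
    if not (0 <= n_incorrect <= max_incorrect):
        raise ValidationError(
            f"n_incorrect={n_incorrect} outside [0, {max_incorrect}]"
        )
    return (n_correct + 1) / (n_incorrect + 1)


def score_knowledge(answers: Sequence[bool]) -> float:
    """Fraction of knowledge items answered correctly.

    ``answers`` must contain exactly :data:`N_KNOWLEDGE_ITEMS` booleans.
    """
    if len(answers) != N_KNOWLEDGE_ITEMS:
        raise ValidationError(
            f"expected {N_KNOWLEDGE_ITEMS} knowledge items, got {len(answers)}"
        )
    return sum(bool(a) for a in answers) / N_KNOWLEDGE_ITEMS
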