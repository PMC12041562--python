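"""Prompt templates and the rank-with-fallback protocol.

Seven template variants are supported.  Q1 is a minimal zero-shot
instruction; Q2 adds patient sex and mode of inheritance; Q3 extends Q2
with an instruction to fall back on gene function, expression site and
animal models; Q4 is a one-shot chain-of-thought prompt with a system
"role" preamble that fixes the output format ('Ranked List:' followed by
a numbered list) and instructs the model to place unknown genes on the
last rank.  Three wording variants of Q2 swap the word "symptoms" for
"signs and symptoms" (Q2_sign) or "phenotypes" (Q2_pheno), or spell out
full gene names instead of symbols (Q2_fullnames).

Rendering is a pure, byte-exact substitution of the stored template:
phenotype labels and gene symbols are joined with ", " by default, sex
replaces the [male/female] placeholder, and the mode of inheritance
replaces [mode of inheritance/genetic] — falling back to the literal
token "genetic" when the case carries none.  Templates that require sex
fail loudly when it is absent; defaults are never invented.

``run_with_fallback`` implements the two-stage protocol in which a
secondary template is issued once when the primary response yields no
recoverable ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Optional

from .benchmark import EvaluationCase

__all__ = [
    "TEMPLATE_IDS",
    "PromptTemplate",
    "RenderedPrompt",
    "template_body",
    "render",
    "run_with_fallback",
]

#: template id -> (base file stem, needs sex/MOI, token replacement)
_SPECS: dict[str, tuple[str, bool, Optional[tuple[str, str]]]] = {
    "Q1": ("q1", False, None),
    "Q2": ("q2", True, None),
    "Q3": ("q3", True, None),
    "Q4": ("q4", True, None),
    "Q2_sign": ("q2", True, ("symptoms", "signs and symptoms")),
    "Q2_pheno": ("q2", True, ("symptoms", "phenotypes")),
    "Q2_fullnames": ("q2", True, None),
}

TEMPLATE_IDS = tuple(_SPECS)

ZERO_SHOT = ("Q1", "Q2", "Q3", "Q2_sign", "Q2_pheno", "Q2_fullnames")
ONE_SHOT_COT = ("Q4",)


@dataclass(frozen=True)
class PromptTemplate:
    template_id: str
    shot_type: str
    body: str
    system_preamble: Optional[str] = None


@dataclass(frozen=True)
class RenderedPrompt:
    case_id: str
    template_id: str
    text: str
    system_preamble: Optional[str] = None


def _read_template(stem: str) -> str:
    return (
        resources.files("phenoprio.templates").joinpath(f"{stem}.txt").read_text()
    )


def template_body(template_id: str) -> PromptTemplate:
    """Load the stored template for ``template_id`` (word variants applied)."""
    if template_id not in _SPECS:
        raise ValueError(f"unknown template id {template_id!r}")
    stem, _, replacement = _SPECS[template_id]
    body = _read_template(stem)
    preamble = _read_template("q4_system") if template_id == "Q4" else None
    if replacement is not None:
        body = body.replace(*replacement)
    shot = "one_shot_cot" if template_id in ONE_SHOT_COT else "zero_shot"
    return PromptTemplate(template_id, shot, body, preamble)


def render(
    template_id: str,
    case: EvaluationCase,
    separator: str = ", ",
    full_gene_names: Optional[Mapping[str, str]] = None,
) -> RenderedPrompt:
    """Instantiate a template for one evaluation case.

    The Q4 system preamble is kept verbatim, including its generic
    one-shot example — its placeholders are not substituted, so each
    candidate gene appears exactly once in the user text.
    """
    tmpl = template_body(template_id)
    _, needs_sex, _ = _SPECS[template_id]
    if needs_sex and not case.sex:
        raise ValueError(
            f"template {template_id} requires the 'sex' field, "
            f"absent from case {case.case_id}"
        )

    genes = list(case.genes)
    if template_id == "Q2_fullnames":
        if full_gene_names is None:
            raise ValueError("Q2_fullnames requires a full_gene_names mapping")
        missing = [g for g in genes if g not in full_gene_names]
        if missing:
            raise ValueError(f"full_gene_names missing entries for {missing}")
        genes = [full_gene_names[g] for g in genes]

    text = tmpl.body
    text = text.replace("[phenotypes]", separator.join(case.phenotypes))
    text = text.replace("[genes]", separator.join(genes))
    if "[male/female]" in text:
        text = text.replace("[male/female]", case.sex)
    text = text.replace("[mode of inheritance/genetic]", case.moi or "genetic")
    return RenderedPrompt(case.case_id, template_id, text, tmpl.system_preamble)


def run_with_fallback(
    primary_id: str,
    fallback_id: str,
    case: EvaluationCase,
    ranker: Callable,
    parser: Callable,
    **render_options,
):
    """Issue the primary template; fall back once if no list is recovered.

    ``ranker(case, rendered_prompt)`` must return an object with a
    ``raw_text`` attribute; ``parser(raw_text, input_genes)`` must return
    a parse with a ``failed`` flag.  Returns ``(parse, used_template_id)``;
    when both templates fail, the fallback's (failed) parse is returned.
    """
    genes = set(case.genes)
    primary = ranker(case, render(primary_id, case, **render_options))
    parsed = parser(primary.raw_text, genes)
    if not parsed.failed:
        return parsed, primary_id
    fallback = ranker(case, render(fallback_id, case, **render_options))
    return parser(fallback.raw_text, genes), fallback_id
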