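"""Few-shot prompt assembly for LLM-driven model extraction, and validation
of candidate model text coming back from such a system.

Only the template machinery lives here: the prompt is a deterministic
concatenation of (a) a task description, (b) an exemplar passage with its
reaction-list transcription, and (c) the target passage to transcribe.  No
network service is ever contacted; callers paste the prompt into whatever
system they use and feed the output to :func:`validate_llm_output`, which
flags the structural omissions such systems typically make (species with no
sink or source, loops left thermodynamically unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import thermo
from .compiler import compile_model
from .dsl import DslError, Issue, ModelParseError, ParsedModel, parse_line, parse_model, validate_model

__all__ = ["PromptTemplate", "build_llm_prompt", "validate_llm_output"]

TASK_INSTRUCTION = (
    "Extract the biochemical reactions mentioned in a given passage and "
    "list them in the specified format, one reaction per line."
)


@dataclass(frozen=True)
class PromptTemplate:
    task_description: str
    exemplar_passage: str
    exemplar_model_text: str
    target_passage: str


def build_llm_prompt(template: PromptTemplate) -> str:
    """Assemble the three-part prompt; the exemplar reaction list must parse."""
    for name in ("task_description", "exemplar_passage", "exemplar_model_text", "target_passage"):
        if not getattr(template, name).strip():
            raise ValueError(f"prompt template field {name!r} is empty")
    try:
        parse_model(template.exemplar_model_text, source_name="<exemplar>")
    except ModelParseError as e:
        raise ValueError(f"exemplar model text does not parse: {e}") from None
    return (
        "## Task\n"
        f"{template.task_description.strip()}\n"
        f"{TASK_INSTRUCTION}\n\n"
        "## Example passage\n"
        f"{template.exemplar_passage.strip()}\n\n"
        "## Example reaction list\n"
        f"{template.exemplar_model_text.strip()}\n\n"
        "## Passage\n"
        f"{template.target_passage.strip()}\n"
    )


def validate_llm_output(candidate_text: str):
    """Parse candidate model text leniently and report everything wrong with it.

    Returns ``(model_or_None, issues)``.  Unparseable lines become issues and
    the remainder is still parsed; on a parseable model, static validation
    issues are extended with thermodynamic warnings (unconstrained loops) and
    dead-end warnings (species produced but never reverted or degraded) — the
    classes of omission that typically need manual correction.
    """
    issues: list[Issue] = []
    good_lines: list[str] = []
    for i, line in enumerate(candidate_text.splitlines(), start=1):
        try:
            parse_line(line, i)
        except DslError as e:
            issues.append(Issue("error", i, f"unparseable line {line.strip()!r}: {e.message}"))
            continue
        good_lines.append(line)
    model: ParsedModel | None = None
    try:
        model = parse_model("\n".join(good_lines), source_name="<llm output>")
    except ModelParseError as e:
        issues.extend(Issue("error", err.line_number, err.message) for err in e.errors)
        return None, issues
    issues.extend(validate_model(model))

    # dead ends: produced species that are never consumed, reverted or degraded
    consumed = {s for r in model.reactions for s in r.reactants}
    produced = {s for r in model.reactions for s in r.products}
    for sp in sorted(produced - consumed):
        issues.append(
            Issue("warning", 0, f"{sp} is produced but never reverts, degrades or reacts further")
        )
    # thermodynamics: loops whose constants are not yet tied by detailed balance
    try:
        compiled = compile_model(model)
        cycles = thermo.cycle_basis(thermo.build_reversible_graph(compiled))
        for cyc in cycles:
            rxns = ", ".join(f"r{e + 1}" for e, _ in cyc.edges)
            issues.append(
                Issue("warning", 0,
                      f"reversible loop ({rxns}) requires a detailed-balance constraint")
            )
    except Exception as e:  # compile problems reported, not raised
        issues.append(Issue("error", 0, f"model does not compile: {e}"))
    return model, issues
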