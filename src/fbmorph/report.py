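"""Prompt assembly and narrative risk reports.

Builds the two-message chat prompt (a system role plus a user message of
three labelled blocks: operator description, measurement summary,
normative airway dimensions), exposes a pluggable chat-completion client
contract, and renders a deterministic offline narrative from a risk
profile so the whole pipeline runs with zero network access. Every
report records its provenance (prompt hash, model id or template
version); generation parameters and model names live in config, and the
narrative always carries a decision-support disclaimer — these outputs
are not autonomous clinical judgments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Protocol

from .airway import AirwayReferenceSet, to_prompt_block
from .errors import ReportValidationError, TransportError
from .image import Shape2DDescriptors
from .mesh import Shape3DDescriptors
from .risk import RiskProfile

__all__ = [
    "ReportConfig",
    "PromptBundle",
    "NarrativeReport",
    "measurement_summary",
    "build_prompt",
    "offline_narrative",
    "ChatCompletionClient",
    "StubChatClient",
    "OpenAIHTTPClient",
    "run_llm",
    "generate_report",
    "request_body",
    "DISCLAIMER",
]

SYSTEM_ROLE = "expert paediatric otolaryngologist and biomedical engineer"

DISCLAIMER = (
    "Decision-support output, not an autonomous clinical judgment; expert "
    "verification is required."
)

TEMPLATE_VERSION = "offline-1.0"

# every measurement the user prompt must enumerate, in fixed order
_SUMMARY_FIELDS_3D = [
    ("volume_mm3", "3D volume", "mm^3"),
    ("surface_area_mm2", "surface area", "mm^2"),
    ("l1_mm", "principal axis length L1", "mm"),
    ("l2_mm", "principal axis length L2", "mm"),
    ("l3_mm", "principal axis length L3", "mm"),
    ("elongation", "elongation", ""),
    ("flatness", "flatness", ""),
    ("sphericity", "sphericity", ""),
    ("convexity_ratio", "convexity ratio", ""),
    ("sharp_edge_count", "sharp edge count", "edges"),
    ("min_dihedral_deg", "minimum dihedral angle", "deg"),
    ("mass_g", "mass", "g"),
]
_SUMMARY_FIELDS_2D = [
    ("area_mm2", "silhouette area", "mm^2"),
    ("perimeter_mm", "perimeter", "mm"),
    ("feret_max_mm", "major (max Feret) diameter", "mm"),
    ("feret_min_mm", "minor (min Feret) diameter", "mm"),
    ("aspect_ratio", "aspect ratio", ""),
    ("circularity", "circularity", ""),
    ("solidity", "solidity", ""),
    ("min_curvature_radius_mm", "minimum curvature radius", "mm"),
]


@dataclass
class ReportConfig:
    """Generation parameters and model preference (config, not code)."""

    temperature: float = 0.5
    max_completion_tokens: int = 5000
    model_preference: list[str] = field(
        default_factory=lambda: ["gpt-5-pro", "gpt-5.1"]
    )

    def to_dict(self) -> dict:
        return asdict(self)


def _fmt_value(v) -> str:
    if v is None:
        return "not measured"
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)


def measurement_summary(
    d3: Shape3DDescriptors | None, d2: Shape2DDescriptors | None
) -> str:
    """Deterministic enumeration of every reportable measurement.

    Fields are listed in fixed order with units and two-decimal rounding;
    a missing descriptor block or field renders as "not measured", never
    omitted.
    """
    d3d = d3.to_dict() if d3 is not None else {}
    d2d = d2.to_dict() if d2 is not None else {}
    lines = ["Quantitative measurements of the object:"]
    for key, label, unit in _SUMMARY_FIELDS_3D:
        suffix = f" {unit}" if unit and d3d.get(key) is not None else ""
        lines.append(f"- {label}: {_fmt_value(d3d.get(key))}{suffix}")
    if d3 is not None:
        lines.append(
            f"- surface-to-volume ratio A/V: "
            f"{_fmt_value(d3d.get('surface_to_volume_per_mm'))} mm^-1"
        )
    lines.append("2D silhouette-derived measures:")
    for key, label, unit in _SUMMARY_FIELDS_2D:
        suffix = f" {unit}" if unit and d2d.get(key) is not None else ""
        lines.append(f"- {label}: {_fmt_value(d2d.get(key))}{suffix}")
    return "\n".join(lines) + "\n"


@dataclass
class PromptBundle:
    """Two-message prompt: system role + three labelled user blocks."""

    system_text: str
    user_blocks: tuple[str, str, str]  # description, summary, normative
    generation_params: dict
    model_preference: list[str]

    def __post_init__(self) -> None:
        if len(self.user_blocks) != 3:
            raise ReportValidationError("exactly three user blocks required")
        for i, block in enumerate(self.user_blocks):
            if not block or not block.strip():
                raise ReportValidationError(f"user block {i + 1} is empty")

    @property
    def user_text(self) -> str:
        labels = (
            "OBJECT DESCRIPTION (operator)",
            "QUANTITATIVE MEASUREMENTS",
            "NORMATIVE AIRWAY DIMENSIONS",
        )
        parts = [
            f"=== {label} ===\n{block.rstrip()}"
            for label, block in zip(labels, self.user_blocks)
        ]
        return "\n\n".join(parts) + "\n"

    @property
    def messages(self) -> list[dict]:
        return [
            {"role": "system", "content": self.system_text},
            {"role": "user", "content": self.user_text},
        ]

    def canonical_json(self) -> bytes:
        payload = {
            "system_text": self.system_text,
            "user_blocks": list(self.user_blocks),
            "generation_params": self.generation_params,
            "model_preference": self.model_preference,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json()).hexdigest()


def build_prompt(
    description: str,
    summary: str,
    normative: str,
    config: ReportConfig | None = None,
) -> PromptBundle:
    """Assemble the prompt bundle from the three information blocks."""
    config = config or ReportConfig()
    system_text = (
        f"You are an {SYSTEM_ROLE}. Provide a concise but comprehensive risk "
        "assessment of a foreign body entering a child's airway. Consider: "
        "the child's age and sex; the object's dimensions, shape, and "
        "sharpness; the likely site of lodgment; possible complications "
        "including obstruction, mucosal injury, and aspiration; preventive "
        "recommendations; and evidence-based reasoning. Avoid overconfidence "
        "and state uncertainty where the data do not support firm conclusions."
    )
    return PromptBundle(
        system_text=system_text,
        user_blocks=(description, summary, normative),
        generation_params={
            "temperature": config.temperature,
            "max_completion_tokens": config.max_completion_tokens,
        },
        model_preference=list(config.model_preference),
    )


@dataclass
class NarrativeReport:
    """Narrative risk assessment with structured sections and provenance."""

    source: str  # "llm" | "offline-template"
    text: str
    structured_sections: dict
    provenance: dict

    def __post_init__(self) -> None:
        required = (
            "dimension_comparison", "lodgment_inference",
            "complications", "prevention",
        )
        for key in required:
            if not self.structured_sections.get(key, "").strip():
                raise ReportValidationError(f"section {key!r} is empty")

    def to_markdown(self) -> str:
        titles = {
            "dimension_comparison": "Dimension comparison",
            "lodgment_inference": "Likely lodgment",
            "complications": "Possible complications",
            "prevention": "Prevention",
        }
        parts = [f"# Aspiration-risk narrative ({self.source})", ""]
        for key, title in titles.items():
            parts += [f"## {title}", "", self.structured_sections[key].rstrip(), ""]
        parts += ["---", DISCLAIMER, ""]
        return "\n".join(parts)

    def to_dict(self) -> dict:
        return asdict(self)


def offline_narrative(
    profile: RiskProfile,
    ref: AirwayReferenceSet,
    description: str | None = None,
) -> NarrativeReport:
    """Deterministic template narrative rendered from the risk profile.

    A pure function of its inputs: identical profiles produce
    byte-identical reports. Used when no chat client is supplied or as
    the fallback when every configured model fails.
    """
    trig = [i for i in profile.indicators if i.triggered]
    not_ev = [i for i in profile.indicators if i.direction == "not_evaluable"]

    dim_lines = []
    for i in profile.indicators:
        if i.direction == "not_evaluable":
            dim_lines.append(f"- {i.id}: not evaluable (missing measurement).")
            continue
        m = _fmt_value(i.measurement)
        dim_lines.append(
            f"- {i.id}: measurement {m} {i.measurement_units} {i.direction} "
            f"threshold {i.threshold} {i.threshold_units} ({i.provenance})."
        )
    dimension_comparison = "\n".join(dim_lines)

    lodg = [
        f"Shape class: {profile.shape_class}. "
        f"Overall qualitative tier: {profile.overall_tier}."
    ]
    if trig:
        lodg.append(
            "Triggered indicators: " + ", ".join(i.id for i in trig) + "."
        )
    lodg.extend(profile.evidence_notes)
    lodgment_inference = "\n".join(lodg)

    comp = []
    if any(i.id in ("sharp_edge_hazard", "sharp_tip_hazard") for i in trig):
        comp.append(
            "Sharp features raise the risk of mucosal laceration and "
            "focal-pressure injury during transit or extraction."
        )
    if any(i.id in ("glottic_ap_traversal", "cross_section_traversal") for i in trig):
        comp.append(
            "Airway entry is plausible in a favourable orientation; partial "
            "or complete obstruction may follow if the object rotates at a "
            "narrow level."
        )
    if any(i.id == "ett_obstruction" for i in trig):
        comp.append(
            "The minor dimension matches the internal bore of an "
            "age-appropriate endotracheal tube and could obstruct it."
        )
    if not comp:
        comp.append(
            "No triggered hazard indicator; residual aspiration risk remains "
            "for any small object within reach of a young child."
        )
    complications = "\n".join(comp)

    prevention = (
        "Keep objects of this size and shape out of reach of young children; "
        "flag similar morphometric profiles in product-safety surveillance; "
        "during extraction, control the sharp end first to protect the "
        "mucosa. " + DISCLAIMER
    )
    if not_ev:
        prevention += (
            " Note: " + ", ".join(i.id for i in not_ev)
            + " could not be evaluated from the supplied measurements."
        )

    sections = {
        "dimension_comparison": dimension_comparison,
        "lodgment_inference": lodgment_inference,
        "complications": complications,
        "prevention": prevention,
    }
    text = "\n\n".join(
        f"[{k}]\n{v}" for k, v in sections.items()
    )
    return NarrativeReport(
        source="offline-template",
        text=text,
        structured_sections=sections,
        provenance={
            "template_version": TEMPLATE_VERSION,
            "airway_table_version": ref.version,
            "tier_rule_version": profile.config.get("tier_rule_version"),
        },
    )


# ---------------------------------------------------------------------------
# chat-completion client contract


class ChatCompletionClient(Protocol):
    """Anything that can answer a two-message chat prompt."""

    def complete(self, model: str, messages: list[dict], params: dict) -> str:
        """Return the completion text, or raise on failure."""
        ...


def request_body(bundle: PromptBundle, model: str) -> bytes:
    """Canonical JSON request body (byte-stable for identical bundles)."""
    payload = {
        "model": model,
        "messages": bundle.messages,
        **bundle.generation_params,
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()


class StubChatClient:
    """Canned-response client for tests and offline demos.

    ``fail_models`` simulates per-model availability failures so fallback
    behaviour is exercisable without a network.
    """

    def __init__(self, response_text: str = "(stub response)", fail_models=()):
        self.response_text = response_text
        self.fail_models = set(fail_models)
        self.requests: list[bytes] = []

    def complete(self, model: str, messages: list[dict], params: dict) -> str:
        if model in self.fail_models:
            raise RuntimeError(f"model {model!r} unavailable")
        self.requests.append(
            json.dumps(
                {"model": model, "messages": messages, **params},
                sort_keys=True, separators=(",", ":"),
            ).encode()
        )
        return self.response_text


class OpenAIHTTPClient:
    """Minimal chat-completions HTTP client (stdlib transport).

    POSTs to ``{base_url}/chat/completions``; the API key is read from the
    environment at call time and never stored or logged.
    """

    def __init__(
        self,
        base_url: str = "https://api.openai.com/v1",
        api_key_env: str = "OPENAI_API_KEY",
        timeout_s: float = 120.0,
    ):
        self.base_url = base_url.rstrip("/")
        self.api_key_env = api_key_env
        self.timeout_s = timeout_s

    def __repr__(self) -> str:  # never expose credentials
        return f"OpenAIHTTPClient(base_url={self.base_url!r})"

    def complete(self, model: str, messages: list[dict], params: dict) -> str:
        import os
        import urllib.request

        key = os.environ.get(self.api_key_env)
        if not key:
            raise RuntimeError(f"environment variable {self.api_key_env} not set")
        body = json.dumps(
            {"model": model, "messages": messages, **params},
            sort_keys=True, separators=(",", ":"),
        ).encode()
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=body,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {key}",
            },
            method="POST",
        )
        with urllib.request.urlopen(req, timeout=self.timeout_s) as resp:
            data = json.loads(resp.read())
        return data["choices"][0]["message"]["content"]


def run_llm(bundle: PromptBundle, client: ChatCompletionClient) -> NarrativeReport:
    """Try each preferred model in order; wrap the first success.

    Raises :class:`TransportError` listing the attempted models when all
    fail. The report text is placed in every structured section slot it
    plausibly fills; narrative structuring of free-form model output is
    intentionally minimal.
    """
    errors = []
    for model in bundle.model_preference:
        try:
            text = client.complete(model, bundle.messages, bundle.generation_params)
        except Exception as exc:
            errors.append(f"{model}: {exc}")
            continue
        sections = dict.fromkeys(
            ("dimension_comparison", "lodgment_inference",
             "complications", "prevention"),
            text,
        )
        return NarrativeReport(
            source="llm",
            text=text,
            structured_sections=sections,
            provenance={
                "model_id": model,
                "bundle_sha256": bundle.sha256,
                "generation_params": bundle.generation_params,
            },
        )
    raise TransportError(
        "all models failed: " + "; ".join(errors),
        attempted_models=list(bundle.model_preference),
    )


def generate_report(
    profile: RiskProfile,
    ref: AirwayReferenceSet,
    description: str = "(no operator description provided)",
    d3: Shape3DDescriptors | None = None,
    d2: Shape2DDescriptors | None = None,
    client: ChatCompletionClient | None = None,
    config: ReportConfig | None = None,
) -> NarrativeReport:
    """End-to-end report step: build the prompt, query the client if one
    is supplied, fall back to the offline template otherwise or on
    transport failure (recorded in provenance)."""
    summary = measurement_summary(d3, d2)
    normative = to_prompt_block(ref)
    bundle = build_prompt(description, summary, normative, config)
    if client is not None:
        try:
            return run_llm(bundle, client)
        except TransportError as exc:
            report = offline_narrative(profile, ref, description)
            report.provenance["fallback_reason"] = str(exc)
            report.provenance["attempted_models"] = exc.attempted_models
            report.provenance["bundle_sha256"] = bundle.sha256
            return report
    report = offline_narrative(profile, ref, description)
    report.provenance["bundle_sha256"] = bundle.sha256
    return report
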