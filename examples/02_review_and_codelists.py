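"""From search hits to tiered, reviewed code lists.

Exports a review template, simulates the expert labelling step, builds a
conservative (diagnosis-only) and a speculative list, and checks the tier
containment relations against a QOF-style reference list.
"""

from codelistkit import (
    CodeList,
    ReviewRow,
    build_codelist,
    build_query,
    check_supersets,
    lookup_from_records,
    make_review_template,
    run_search,
)

table = lookup_from_records(
    [
        ("E100.00", "Schizophrenia"),
        ("E110.00", "Bipolar affective disorder"),
        ("E120.00", "Psychosis annual review"),
        ("665..00", "Psychosis screening invite"),
        ("T880.00", "Sunstroke"),
    ]
)
result = run_search(build_query(word_terms=["schizo", "bipolar", "psycho", "stroke"]), table)
template = make_review_template(result)
print(f"{len(template)} candidate codes exported for review (all categories empty)\n")

# An expert panel would label the exported file by hand; emulate that here.
labels = {
    "E100.00": "diagnosis",
    "E110.00": "diagnosis",
    "E120.00": "management_or_symptom",
    "665..00": "screening",
    "T880.00": "not_relevant",  # the classic substring false positive
}
reviewed = [ReviewRow(**{**r.__dict__, "category": labels[r.code]}) for r in template]

conservative = build_codelist(reviewed, "conservative", name="smi-conservative")
speculative = build_codelist(reviewed, "speculative", name="smi-speculative")
print(f"conservative (diagnosis only): {sorted(conservative.codes)}")
print(f"speculative (all substantive categories): {sorted(speculative.codes)}\n")
# The conservative list keeps only codes each individually diagnostic; the
# speculative list adds ambiguous-but-suggestive management/screening codes.

qof = CodeList(
    name="qof-smi", tier="qof",
    entries={"E100.00": "diagnosis", "E110.00": "diagnosis", "9h92.00": "diagnosis"},
)
report = check_supersets(qof, conservative, speculative,
                         qof_exception_codes={"9h92.00"})
print(f"superset relations hold: {report.passed}")
# 9h92.00 is an exception-reporting code (patient unsuitable for the
# indicator), so it is exempt from the containment requirement.
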