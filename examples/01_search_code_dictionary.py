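"""Search a small code dictionary with word- and code-stubs.

Builds a five-row Read-style dictionary, then runs three searches showing
the matching rules: code stubs match as prefixes (a subtree search in a
hierarchical terminology), word stubs match as description substrings
(deliberately over-inclusive), and dollar-prefixed stubs exclude rows.
"""

from codelistkit import build_query, lookup_from_records, run_search

table = lookup_from_records(
    [
        ("H331.11", "Late onset asthma"),
        ("8H33.00", "Day hospital care"),
        ("J083300", "Ludwig's angina"),
        ("E273100", "Head-banging"),
        ("13HV400", "Seven year itch—marital"),
    ]
)

print("code stub 'H33' (prefix match):")
print(run_search(build_query(code_terms=["H33"]), table).to_frame(), "\n")
# Only H331.11 is returned: 8H33.00 contains H33 but not at the start.

print("word stub 'angin' (substring match):")
print(run_search(build_query(word_terms=["angin"]), table).to_frame(), "\n")
# Both Ludwig's angina and Head-banging match — the search is intentionally
# over-inclusive; false positives are removed later by expert review.

splen = lookup_from_records(
    [("J690.00", "Splenomegaly"), ("J691.00", "Hypersplenism"), ("7J36.00", "Splenectomy")]
)
print("'splen' with exclusion '$hypersplenism':")
print(run_search(build_query(word_terms=["splen", "$hypersplenism"]), splen).to_frame())
# The hypersplenism row is vetoed, shrinking the list the reviewers must read.
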