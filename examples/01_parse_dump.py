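"""Parse a knowledge-base dump and summarize its contents.

Generates a small synthetic dump first, then parses it the way one would
parse a real quarterly download.
"""

import tempfile

from aoplink import extract_chemicals, parse_aopwiki_xml
from aoplink.aopwiki import key_events_by_level
from aoplink.synth import SyntheticConfig, generate_bundle

with tempfile.TemporaryDirectory() as td:
    paths, _ = generate_bundle(SyntheticConfig(seed=42), td)
    dataset = parse_aopwiki_xml(paths["xml"])

    summary = extract_chemicals(dataset)
    print(f"key events: {len(dataset.key_events)}")
    print(f"  by level: {key_events_by_level(dataset)}")
    print(f"relationships: {len(dataset.kers)}")
    print(f"stressors: {summary.n_stressors}, unique chemicals: "
          f"{summary.n_unique_chemicals}, unique CAS: {summary.n_unique_cas}")
    # stressor/chemical/CAS counts deduplicate: several stressors may share
    # one chemical, and a chemical may lack a CAS registry number.
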