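"""Plain-text normalization of marked-up description fields.

Key-event and relationship descriptions in knowledge-base dumps carry embedded
HTML (paragraphs, lists, inline formatting) and occasional wiki markup. All
downstream text matching operates on a normalized plain-text rendering:
tags removed, character entities decoded, whitespace runs collapsed to single
spaces, leading/trailing whitespace stripped.
"""

from __future__ import annotations

import re
from html import unescape
from html.parser import HTMLParser

_WS_RUN = re.compile(r"\s+")
# crude wiki-link markup: [[target|label]] or [[target]]
_WIKI_LINK = re.compile(r"\[\[(?:[^|\]]*\|)?([^\]]*)\]\]")


class _TextExtractor(HTMLParser):
    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.parts: list[str] = []

    def handle_data(self, data: str) -> None:
        self.parts.append(data)

    def handle_starttag(self, tag: str, attrs) -> None:
        # block-ish tags act as word separators so "<p>a</p><p>b</p>" -> "a b"
        self.parts.append(" ")

    def handle_endtag(self, tag: str) -> None:
        self.parts.append(" ")


def strip_markup(text: str | None) -> str:
    """Render marked-up text as normalized plain text.

    Removes HTML tags (treating them as word separators), decodes character
    entities, unwraps ``[[...]]`` wiki links to their labels, and collapses
    all whitespace runs to single spaces.
    """
    if not text:
        return ""
    text = _WIKI_LINK.sub(r"\1", text)
    if "<" in text or "&" in text:
        extractor = _TextExtractor()
        extractor.feed(text)
        extractor.close()
        text = "".join(extractor.parts)
        # a second decode pass handles double-escaped entities from XML embedding
        text = unescape(text)
    return _WS_RUN.sub(" ", text).strip()


def normalize_whitespace(text: str | None) -> str:
    """Collapse whitespace runs to single spaces and strip the ends."""
    if not text:
        return ""
    return _WS_RUN.sub(" ", text).strip()
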