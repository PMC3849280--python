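"""Aho–Corasick multi-pattern string automaton.

Dictionary matching has to locate every occurrence of every surface form of
potentially hundreds of thousands of concept names in time linear in the
sentence length.  A deterministic finite automaton over the pattern set does
exactly that: one pass over the text, following goto/failure transitions,
reports every pattern occurrence at the position where it ends.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, Iterable, Iterator, List, Tuple


class Automaton:
    """Immutable Aho–Corasick automaton over a set of string patterns.

    Build once from the full pattern set, then :meth:`iter_matches` yields
    ``(start, end, pattern)`` for every occurrence, in order of match end.
    """

    def __init__(self, patterns: Iterable[str]):
        # trie: list of {char: state}; one output list of pattern lengths per state
        self._goto: List[Dict[str, int]] = [{}]
        self._out: List[List[int]] = [[]]
        self._fail: List[int] = [0]
        n_patterns = 0
        for pat in sorted(set(patterns)):
            if not pat:
                continue
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(len(pat))
            n_patterns += 1
        self.n_patterns = n_patterns
        self._build_failure_links()

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self._goto[state].items():
                queue.append(child)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                # inherit outputs reachable through the failure chain
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str) -> Iterator[Tuple[int, int, str]]:
        """Yield ``(start, end, pattern)`` for every pattern occurrence."""
        state = 0
        for pos, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for length in self._out[state]:
                start = pos + 1 - length
                yield (start, pos + 1, text[start: pos + 1])

    def __len__(self) -> int:
        return self.n_patterns
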