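"""Small I/O helpers shared by the container modules."""

from __future__ import annotations

import io

from .errors import TruncatedFileError


def read_exact(f, n: int) -> bytes:
    """Read exactly ``n`` bytes or raise :class:`TruncatedFileError`."""
    buf = f.read(n)
    if len(buf) != n:
        raise TruncatedFileError(f"expected {n} bytes, got {len(buf)}")
    return buf


class CountingFile:
    """File wrapper that counts seek and read calls.

    Used by the random-access paths (index fetch, columnar walker) so tests
    and benchmark reports can audit the number of disk operations each access
    strategy performs.
    """

    def __init__(self, f: io.IOBase):
        self._f = f
        self.seeks = 0
        self.reads = 0
        self.bytes_read = 0

    def seek(self, pos: int, whence: int = 0) -> int:
        self.seeks += 1
        return self._f.seek(pos, whence)

    def read(self, n: int = -1) -> bytes:
        self.reads += 1
        buf = self._f.read(n)
        self.bytes_read += len(buf)
        return buf

    def tell(self) -> int:
        return self._f.tell()

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False
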