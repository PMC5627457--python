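"""Video input/output for top-down arena recordings.

The tracker consumes any iterable of 2-D uint8 grayscale frames.  Three
on-disk forms are supported:

* uncompressed 8-bit AVI (RIFF with raw DIB frames) — written and read by
  this module; plays in VLC/ffmpeg and round-trips bit-exactly, which the
  deterministic-pipeline guarantees rely on;
* multi-page TIFF stacks (via tifffile);
* ``.npy`` arrays of shape (n_frames, height, width).

24-bit RGB DIB frames are accepted on read and converted to grayscale by
the Rec. 601 luminance weights.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_LUMA = np.array([0.114, 0.587, 0.299])  # DIB stores BGR


def _pad4(n: int) -> int:
    return (n + 3) & ~3


# ---------------------------------------------------------------------------
# AVI writing

def write_avi(path, frames, fps: float = 30.0) -> int:
    """Write grayscale uint8 frames as an uncompressed 8-bit palettized AVI.

    ``frames`` is any iterable of equal-shaped (h, w) uint8 arrays.
    Returns the number of frames written.
    """
    frames = iter(frames)
    try:
        first = np.asarray(next(frames))
    except StopIteration:
        raise ValueError("no frames to write")
    if first.ndim != 2 or first.dtype != np.uint8:
        raise ValueError("frames must be 2-D uint8 arrays")
    h, w = first.shape
    stride = _pad4(w)
    frame_bytes = stride * h

    def dib(frame: np.ndarray) -> bytes:
        if frame.shape != (h, w):
            raise ValueError("frame size changed mid-video")
        padded = np.zeros((h, stride), dtype=np.uint8)
        padded[:, :w] = frame[::-1]  # DIB rows are bottom-up
        return padded.tobytes()

    rate = int(round(fps * 1000))
    scale = 1000
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes,
                       0, 0, 256, 0)
    strf = b"strf" + struct.pack("<I", len(bmih) + len(palette)) + bmih + palette
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(b"RIFF\0\0\0\0AVI ")
        # hdrl list -----------------------------------------------------
        avih = struct.pack("<IIIIIIIIIIIIII",
                           int(1e6 / fps), frame_bytes * int(round(fps)), 0,
                           0x10, 0, 0, 1, frame_bytes, w, h, 0, 0, 0, 0)
        strh = (b"vidsDIB " + struct.pack("<IHHIIIIIIii",
                                          0, 0, 0, 0, scale, rate, 0, 0,
                                          frame_bytes, -1, 0)
                + struct.pack("<HHHH", 0, 0, w, h))
        strl = b"LIST" + struct.pack(
            "<I", 4 + 8 + len(strh) + len(strf)) + b"strl" \
            + b"strh" + struct.pack("<I", len(strh)) + strh + strf
        hdrl = b"LIST" + struct.pack(
            "<I", 4 + 8 + len(avih) + len(strl)) + b"hdrl" \
            + b"avih" + struct.pack("<I", len(avih)) + avih + strl
        fh.write(hdrl)
        # movi list -----------------------------------------------------
        movi_size_pos = fh.tell() + 4
        fh.write(b"LIST\0\0\0\0movi")
        index: list[tuple[int, int]] = []
        n = 0
        offset = 4  # idx1 offsets are relative to the 'movi' fourcc
        frame = first
        while True:
            data = dib(np.asarray(frame))
            fh.write(b"00db" + struct.pack("<I", len(data)) + data)
            index.append((offset, len(data)))
            offset += 8 + len(data)
            n += 1
            try:
                frame = next(frames)
            except StopIteration:
                break
        movi_end = fh.tell()
        # idx1 ----------------------------------------------------------
        fh.write(b"idx1" + struct.pack("<I", 16 * n))
        for off, ln in index:
            fh.write(b"00db" + struct.pack("<III", 0x10, off, ln))
        riff_end = fh.tell()
        # patch sizes and frame counts ----------------------------------
        fh.seek(4)
        fh.write(struct.pack("<I", riff_end - 8))
        fh.seek(movi_size_pos)
        fh.write(struct.pack("<I", movi_end - movi_size_pos - 4))
        avih_frames_pos = 12 + 8 + 4 + 8 + 16
        fh.seek(avih_frames_pos)
        fh.write(struct.pack("<I", n))
        strh_len_pos = 12 + 8 + 4 + 8 + len(avih) + 8 + 4 + 8 + 4 + 4 + 4 + 4 + 4 + 4 + 4 + 4
        fh.seek(strh_len_pos)
        fh.write(struct.pack("<I", n))
    return n


# ---------------------------------------------------------------------------
# AVI reading

class AviReader:
    """Streaming reader for uncompressed ('DIB ') AVI files."""

    def __init__(self, path):
        self.path = Path(path)
        self._fh = open(self.path, "rb")
        self._parse()

    def _parse(self) -> None:
        fh = self._fh
        head = fh.read(12)
        if len(head) < 12 or head[:4] != b"RIFF" or head[8:12] != b"AVI ":
            raise IOError(f"{self.path} is not an AVI file")
        self.width = self.height = None
        self.bit_count = None
        self.fps = 30.0
        self._chunks: list[tuple[int, int]] = []  # (file offset, size)
        riff_size = struct.unpack("<I", head[4:8])[0]
        end = 8 + riff_size
        self._walk(fh.tell(), end)
        if self.width is None:
            raise IOError(f"{self.path}: no video stream format found")
        if self.bit_count not in (8, 24):
            raise IOError(f"unsupported bit depth {self.bit_count}; only "
                          "uncompressed 8-bit/24-bit AVI is readable")

    def _walk(self, pos: int, end: int) -> None:
        fh = self._fh
        while pos + 8 <= end:
            fh.seek(pos)
            hdr = fh.read(8)
            if len(hdr) < 8:
                break
            fourcc, size = hdr[:4], struct.unpack("<I", hdr[4:])[0]
            if fourcc in (b"RIFF", b"LIST"):
                self._walk(pos + 12, pos + 8 + size)
            elif fourcc == b"strh":
                data = fh.read(size)
                if data[:4] == b"vids":
                    scale, rate = struct.unpack("<II", data[20:28])
                    if scale:
                        self.fps = rate / scale
            elif fourcc == b"strf" and self.width is None:
                data = fh.read(size)
                (_, w, h, _, bits) = struct.unpack("<IiiHH", data[:16])
                self.width, self.height = w, abs(h)
                self._topdown = h < 0
                self.bit_count = bits
            elif fourcc[2:] in (b"db", b"dc") and fourcc[:2].isdigit():
                if size:
                    self._chunks.append((pos + 8, size))
            pos += 8 + size + (size & 1)

    @property
    def n_frames(self) -> int:
        return len(self._chunks)

    def _decode(self, raw: bytes) -> np.ndarray:
        w, h = self.width, self.height
        if self.bit_count == 8:
            stride = _pad4(w)
            img = np.frombuffer(raw[:stride * h], np.uint8).reshape(h, stride)
            img = img[:, :w]
        else:
            stride = _pad4(w * 3)
            img = np.frombuffer(raw[:stride * h], np.uint8).reshape(h, stride)
            img = img[:, :w * 3].reshape(h, w, 3).astype(float) @ _LUMA
            img = img.round().astype(np.uint8)
        return img if self._topdown else img[::-1]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for off, size in self._chunks:
            self._fh.seek(off)
            yield self._decode(self._fh.read(size))

    def read_all(self) -> np.ndarray:
        return np.stack(list(self))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


# ---------------------------------------------------------------------------
# generic frame sources

def open_frames(path):
    """Open any supported frame container.

    Returns ``(frames, fps)`` where ``frames`` is an iterable of (h, w)
    uint8 arrays and ``fps`` is the container frame rate (None when the
    container does not store one).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".avi":
        reader = AviReader(path)
        return reader, reader.fps
    if suffix in (".tif", ".tiff"):
        import tifffile
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return as_gray(stack), None
    if suffix == ".npy":
        stack = np.load(path)
        return as_gray(stack), None
    raise IOError(f"unsupported video container {suffix!r}; "
                  "use uncompressed .avi, .tif stacks, or .npy")


def as_gray(stack: np.ndarray) -> np.ndarray:
    """Coerce a (n, h, w[, 3]) stack to uint8 grayscale."""
    stack = np.asarray(stack)
    if stack.ndim == 4 and stack.shape[-1] == 3:
        stack = (stack[..., ::-1].astype(float) @ _LUMA).round()
    if stack.dtype != np.uint8:
        stack = np.clip(stack, 0, 255).astype(np.uint8)
    return stack
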