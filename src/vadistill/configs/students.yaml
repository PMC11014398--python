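# Versioned student block tables (inverted-residual bottlenecks, 3x3 depthwise
# convolutions only, ReLU everywhere). Row columns: exp = expansion channels,
# out = output channels, se = squeeze-excite present, stride.
#
# Constraints honored: student1 stems at 16 with bottleneck channels spanning
# 16..512 and 256 channels entering the average pool; student2 has fewer
# bottlenecks and raises the pre-pool width from 256 to 512; student3 stems at
# 4 and spans 4..128; student4 stems at 4, spans 4..64, is shallower, and uses
# a different (front-loaded, flattening) expansion-ratio pattern than the
# escalating pattern shared by students 1-3. Parameter counts follow the
# reference ordering student1 > student2 > student3 > student4 at the same
# orders of magnitude (4.3M / 2.8M / 365k / 37k).
version: 1
students:
  student1:
    stem: 16
    head_hidden: 1280
    blocks:
      - {exp: 16,  out: 16,  se: true,  stride: 1}
      - {exp: 64,  out: 24,  se: false, stride: 2}
      - {exp: 96,  out: 24,  se: false, stride: 1}
      - {exp: 96,  out: 40,  se: true,  stride: 2}
      - {exp: 240, out: 40,  se: true,  stride: 1}
      - {exp: 240, out: 64,  se: true,  stride: 1}
      - {exp: 384, out: 64,  se: true,  stride: 1}
      - {exp: 384, out: 96,  se: true,  stride: 2}
      - {exp: 512, out: 128, se: true,  stride: 1}
      - {exp: 512, out: 160, se: true,  stride: 1}
      - {exp: 512, out: 192, se: true,  stride: 1}
      - {exp: 512, out: 224, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
      - {exp: 512, out: 256, se: true,  stride: 1}
  student2:
    stem: 16
    head_hidden: 1024
    blocks:
      - {exp: 16,  out: 16,  se: true,  stride: 1}
      - {exp: 72,  out: 24,  se: false, stride: 2}
      - {exp: 96,  out: 40,  se: true,  stride: 2}
      - {exp: 240, out: 64,  se: true,  stride: 1}
      - {exp: 384, out: 96,  se: true,  stride: 2}
      - {exp: 512, out: 192, se: true,  stride: 1}
      - {exp: 512, out: 320, se: true,  stride: 1}
      - {exp: 512, out: 512, se: true,  stride: 1}
      - {exp: 512, out: 512, se: true,  stride: 1}
      - {exp: 512, out: 512, se: true,  stride: 1}
  student3:
    stem: 4
    head_hidden: 512
    blocks:
      - {exp: 16,  out: 8,   se: true,  stride: 1}
      - {exp: 48,  out: 16,  se: false, stride: 2}
      - {exp: 64,  out: 24,  se: false, stride: 1}
      - {exp: 96,  out: 32,  se: true,  stride: 2}
      - {exp: 128, out: 48,  se: true,  stride: 1}
      - {exp: 128, out: 64,  se: true,  stride: 1}
      - {exp: 128, out: 64,  se: true,  stride: 1}
      - {exp: 128, out: 96,  se: true,  stride: 2}
      - {exp: 128, out: 96,  se: true,  stride: 1}
      - {exp: 128, out: 128, se: true,  stride: 1}
      - {exp: 128, out: 128, se: true,  stride: 1}
      - {exp: 128, out: 128, se: true,  stride: 1}
      - {exp: 128, out: 128, se: true,  stride: 1}
      - {exp: 128, out: 128, se: true,  stride: 1}
  student4:
    stem: 4
    head_hidden: 96
    blocks:
      - {exp: 16,  out: 8,   se: true,  stride: 1}
      - {exp: 32,  out: 16,  se: false, stride: 2}
      - {exp: 48,  out: 24,  se: true,  stride: 1}
      - {exp: 64,  out: 32,  se: true,  stride: 2}
      - {exp: 64,  out: 48,  se: true,  stride: 1}
      - {exp: 64,  out: 64,  se: true,  stride: 1}
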