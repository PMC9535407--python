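# Unit registry: verbatim unit spelling -> canonical unit + multiplicative factor.
# Canonical units are g (mass) and mm (length).
g: {canonical: g, factor: 1.0}
gram: {canonical: g, factor: 1.0}
grams: {canonical: g, factor: 1.0}
kg: {canonical: g, factor: 1000.0}
kilogram: {canonical: g, factor: 1000.0}
kilograms: {canonical: g, factor: 1000.0}
mg: {canonical: g, factor: 0.001}
mm: {canonical: mm, factor: 1.0}
millimeter: {canonical: mm, factor: 1.0}
millimeters: {canonical: mm, factor: 1.0}
cm: {canonical: mm, factor: 10.0}
centimeter: {canonical: mm, factor: 10.0}
centimeters: {canonical: mm, factor: 10.0}
m: {canonical: mm, factor: 1000.0}
in: {canonical: mm, factor: 25.4}
inch: {canonical: mm, factor: 25.4}
inches: {canonical: mm, factor: 25.4}
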