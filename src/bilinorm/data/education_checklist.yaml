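# Family-education checklist, adapted from NICE neonatal-jaundice
# communication guidance.  Items are grouped by advice tier; the "common"
# block is prepended to every tier.  Bilingual: English (en) and
# Indonesian (id).
languages: [en, id]
common:
  en:
    - "Explain that newborn jaundice is common and usually harmless, but needs monitoring."
    - "Explain what the bilirubin level means and why it is plotted against the baby's age."
    - "Encourage frequent feeding (breastfeeding support if needed)."
  id:
    - "Jelaskan bahwa kuning pada bayi baru lahir sering terjadi dan biasanya tidak berbahaya, tetapi perlu dipantau."
    - "Jelaskan arti kadar bilirubin dan mengapa kadar tersebut dibandingkan dengan usia bayi."
    - "Anjurkan pemberian minum yang sering (dukungan menyusui bila perlu)."
tiers:
  no_treatment:
    - en: "Explain that no treatment is needed at the current bilirubin level."
      id: "Jelaskan bahwa saat ini tidak diperlukan pengobatan pada kadar bilirubin sekarang."
    - en: "Advise the family to watch for deepening jaundice, poor feeding or unusual sleepiness."
      id: "Minta keluarga mengamati kuning yang bertambah, bayi malas minum, atau bayi tampak sangat mengantuk."
    - en: "Arrange follow-up and a repeat bilirubin check as advised by the care team."
      id: "Atur kontrol ulang dan pemeriksaan bilirubin ulang sesuai anjuran tim perawatan."
    - en: "Explain when and whom to contact if the family is worried before the follow-up visit."
      id: "Jelaskan kapan dan kepada siapa keluarga harus menghubungi bila khawatir sebelum jadwal kontrol."
  start_phototherapy:
    - en: "Explain why phototherapy is being started and how it lowers the bilirubin level."
      id: "Jelaskan mengapa fototerapi dimulai dan bagaimana terapi ini menurunkan kadar bilirubin."
    - en: "Reassure the family that phototherapy is safe; eye protection will be used."
      id: "Yakinkan keluarga bahwa fototerapi aman; pelindung mata akan digunakan."
    - en: "Explain that feeding can usually continue, with short breaks from the lights."
      id: "Jelaskan bahwa pemberian minum biasanya dapat dilanjutkan dengan jeda singkat dari lampu terapi."
    - en: "Explain that bilirubin will be re-measured to decide when phototherapy can stop."
      id: "Jelaskan bahwa bilirubin akan diperiksa ulang untuk menentukan kapan fototerapi dapat dihentikan."
  intensive_pt_consider_exchange:
    - en: "Explain that the bilirubin level is high and intensive phototherapy must start immediately."
      id: "Jelaskan bahwa kadar bilirubin tinggi dan fototerapi intensif harus segera dimulai."
    - en: "Explain that an exchange transfusion may be needed if the level does not fall."
      id: "Jelaskan bahwa transfusi tukar mungkin diperlukan bila kadar bilirubin tidak turun."
    - en: "Explain the risk of bilirubin harming the brain if treatment is delayed."
      id: "Jelaskan risiko bilirubin membahayakan otak bila pengobatan ditunda."
    - en: "Discuss follow-up after discharge, including hearing testing and developmental review."
      id: "Diskusikan pemantauan setelah pulang, termasuk pemeriksaan pendengaran dan perkembangan."
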