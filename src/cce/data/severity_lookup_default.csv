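lesion_term,severity
hyperplasia,1
metaplasia,1
dysplasia,1
hyperkeratosis,1
preneoplastic lesion,1
altered foci,1
adenoma,2
papilloma,2
fibroma,2
fibroadenoma,2
lipoma,2
hemangioma,2
polyp,2
keratoacanthoma,2
pheochromocytoma,2
benign tumor,2
benign tumors,2
benign pheochromocytoma,2
carcinoma,3
adenocarcinoma,3
sarcoma,3
fibrosarcoma,3
hemangiosarcoma,3
osteosarcoma,3
mesothelioma,3
leukemia,3
lymphoma,3
glioma,3
malignant pheochromocytoma,3
malignant tumor,3
malignant tumors,3
metastatic,4
metastasizing,4
metastasizing tumors,4
malignant tumors in different organs,4
tumor-bearing animals,5
tumor bearing animals,5
tumour-bearing animals,5
animals with tumors,5
all tumors,5
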